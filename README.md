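# transoval

Simulation of percutaneous transoval needle trajectories: from a cheek entry
point, between maxilla and mandible, through the foramen ovale (FO) into
Meckel's cave — the route used for glycerol injection and other ablative
treatments of trigeminal neuralgia. The package is for researchers studying
the geometry of this approach: it computes, for any coregistered bony scene,
which entry points on the cheek give easy, possible or no access to the cave
through the bony foraminal canal, and where the classical Härtel trigeminal
axis exits the skin (the *Einstichpunkt*).

Because no patient imaging ships with the package, everything runs on a
parametric synthetic skull-base phantom with known ground-truth geometry
(canal pose and calibre, cave position, mandibular ramus, cheek sheet,
landmarks), built as first-class, tested code.

## The model

Entry heights are measured from the **horizontal plane through the angle of
the mouth** (the functional occlusal plane translated to the oral
commissure); heights are signed, + above / − below, and lateral offsets are
in-plane distances from the mouth angle.

For an entry point *e*, rays are cast to a stratified sample
*s₁ … sₙ* (n = 1000) of the FO aperture — the extracranial rim of the
~1 cm bony canal. The **accessible fraction**

    A(e) = #{ i : the ray e → sᵢ reaches the cave before any bone } / n

classifies the entry:

* **easy** — A(e) ≥ ½ and the aperture is distinct (its projected outline
  from *e* is at least 2 mm wide at its narrowest);
* **blocked** — A(e) = 0;
* **possible** — anything in between, including slit-like apertures.

Scanning entries along the line just in front of the anterior edge of the
mandibular ramus yields the **extreme span** (outermost heights with any
access) and the **easy span**, with boundaries bisected to 0.1 mm. Cohort
runs aggregate per-level hit percentages over many sides and the statistics
of the simulated Härtel axis.

Supporting stages: paired-landmark rigid registration (Kabsch on
semicircular-canal points, FRE reporting), NIfTI label-volume I/O, marching
cubes surface extraction, Slicer-style FCSV / JSON landmarks.

## Worked example

```sh
python analysis/03_single_side_analysis.py
```

prints, for the canonical right side:

```
aperture: area 22.4 mm^2, semi-axes 3.21 (ML) x 2.22 (AP) mm
extreme span: -44.6 .. +23.7 mm (width 68.3 mm)
easy span:    -10.5 .. +8.2 mm (width 18.6 mm)
Härtel Einstichpunkt: +4.6 mm relative to the horizontal plane
  axis origin raised 1 mm -> exit at -0.7 mm
  axis origin raised 2 mm -> exit at -6.3 mm
recommended entry (soft-tissue offset 0 mm): -2.0 mm
recommended entry (soft-tissue offset 5 mm): -7.0 mm
```

Reading this: the cave can be reached from cheek heights between −44.6 and
+23.7 mm, but only between −10.5 and +8.2 mm is it *easily* accessible
through half or more of a distinct foramen; the span brackets the −2 mm
optimum. The Härtel axis exits at +4.6 mm, and raising its intracranial
origin by 1–2 mm drops the skin exit by 5–11 mm — the lever-arm effect of
aiming through a ~1 cm canal. With the 5 mm soft-tissue correction the
recommended puncture site is −7 mm.

The same pipeline as a shell tool:

```sh
transoval generate --n 4 --seed 7 --out phantoms/
transoval analyze phantoms/side_00 --out out/
transoval cohort --n 22 --seed 42 --out cohort_out/
```

`analysis/` contains the numbered study drivers: `01` generates the 22-side
cohort, `02` validates registration recovery under fiducial noise, `03` is
the worked example above, `04` runs the cohort aggregation (per-level
hit-percentage curve and span chart with Einstichpunkte), `05` cross-checks
the mesh ray caster against a voxel ray-marching oracle.

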