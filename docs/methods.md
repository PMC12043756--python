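# Methods

## What is being simulated

Percutaneous treatment of trigeminal neuralgia passes a straight needle from
the cheek, between maxilla and mandible, through the foramen ovale (FO) into
Meckel's cave. The FO is not a simple hole but a bony canal on the order of
1 cm long, so the set of cheek entry points from which the cave can be
reached is bounded: too high and the canal forecloses (its projection
narrows to a slit), too low and the posterior canal rim hides the cave, too
lateral and the mandibular ramus is in the way. This package models that
geometry explicitly: given a bony scene, a cave target, a cheek surface and
the clinical measurement frame, it classifies entry points, finds the
accessible and easily-accessible height spans, and simulates the classical
Härtel trigeminal axis and its skin exit (the Einstichpunkt).

All computations are exercised on a parametric synthetic skull-base phantom
with known ground truth; no patient data are used or required.

## The phantom

The phantom is assembled from implicit solids (approximate signed-distance
fields) and surfaced by marching cubes, which guarantees watertight meshes at
a controllable resolution (`mesh_voxel_mm`, default 0.5 mm):

* **Skull-base plate** — an 80 × 80 × 6 mm box (the planum infratemporale /
  middle-fossa floor), pierced by the canal.
* **Foraminal canal** — an elliptical cylinder along a configurable axis,
  default semi-axes 3.2 mm (mediolateral) × 2.2 mm (anteroposterior), length
  10 mm, with a 2.5 mm bony collar so both rims are well defined. The default
  axis points intracranially at 40° elevation, tilted posteriorly and
  slightly medially — the needle travels up-posterior-medial, as in the
  transoval route. Aperture and canal dimensions are literature-plausible
  free parameters: the defaults sit inside published FO ranges, not at any
  particular patient's values.
* **Meckel's cave** — an ellipsoid with semi-axes 5 × 8 × 4.5 mm (ML × AP ×
  SI), placed posterosuperior and slightly medial to the intracranial canal
  exit. The posterior and medial offsets are what produce the clinically
  described regimes: from low entries the posterior rim progressively hides
  the cave, and partially occluded apertures are easier to work through
  medially.
* **Mandibular ramus** — a vertical bone slab lateral to the corridor;
  entries lateral of its anterior face are occluded ("mandible occlusion").
* **Cheek** — an open planar sheet ~70 mm from the extracranial canal exit,
  oriented anterolaterally.
* **Landmarks** — angle of the mouth, a ring of bite-plane (functional
  occlusal) points, the trigeminal-impression midpoint (placed on the
  intracranial extension of the canal axis, ~5 mm deep to the exit — which is
  precisely why Härtel's axis is nearly coaxial with the canal), ≥3
  semicircular-canal stand-in fiducials, and the entry-line anchor 1 mm in
  front of the ramus.

Left sides are generated as exact mirror images of their right-handed twin,
so bilateral pairs are bit-symmetric and all lateral offsets are reported as
absolute values.

### What the phantom does and does not emulate

It reproduces the *geometry classes* of the clinical problem — a finite
oblique canal, a posterosuperior target, lateral occlusion, a measurement
plane on the face — with controllable parameters, so that easy, possible,
blocked, slit-like and rim-occluded regimes all occur and have known ground
truth. It does **not** emulate CT intensities, segmentation noise, the
beveled (non-prismatic) opening of a real FO into the sphenoid surface,
curved cheeks, or deformable soft tissue. Consequences worth noting: with a
prismatic canal the slit-like-projection regime begins farther above the
easy span than in real anatomy, where the beveled extracranial opening is
seen edge-on much sooner; and the phantom's accessible spans are wider than
clinical ones because the cheek sheet is an unbounded plane. Tests passing on
the phantom certify the *machinery* (ray casting, frames, spans, registration)
and the qualitative regime structure — not patient-level numbers.

## Measurement frame

Heights are signed distances from "the horizontal plane through the angle of
the mouth": the least-squares plane of the occlusal points, translated to
pass through the mouth angle, its normal oriented toward the skull-base
fiducial centroid (+ above, − below). Lateral offsets are in-plane Euclidean
distances from the mouth angle (calliper-style, not arc length along the
skin). Heights and all downstream classifications are invariant under joint
rigid motions of the scene.

## Visibility model

The needle is an ideal straight line. For an entry point *e* the aperture —
the extracranial rim of the canal, extracted as the closed intersection loop
of the bone mesh with the plane normal to the canal axis, inset 0.3 mm into
the canal so the slice cuts the cylindrical wall rather than the flat rim
face — is sampled with a stratified jittered grid restricted to the rim
polygon (default n = 1000, fixed seed). A sample *s* is **accessible** when
the first thing the ray *e→s* meets is the cave, not bone. The entry is

* **easy** if the accessible fraction ≥ 0.5 *and* the aperture is distinct —
  its orthographic outline seen from *e* has a minimum caliper width ≥ 2 mm
  (the `slit_threshold`; below it the FO presents as a slit);
* **blocked** if the fraction is 0;
* **possible** otherwise.

The medial fraction is the same statistic restricted to the medial half of
the aperture (split by the half-plane through the centroid normal to the
mediolateral axis of the rim's best-fit ellipse, fitted by the direct
algebraic method). "Half or more of the aperture" is read as the
ray-accessible fraction of aperture samples, not as projected area — the two
coincide for a distinct aperture and the former is what a surgeon's freedom
of needle placement within the foramen actually measures.

Entry lines are scanned on a 1 mm grid (default −45…+30 mm, matching the
span of levels over which hits occur) through the anchor just in front of the
ramus, then each span boundary (outermost accessible heights; easy-span
bounds) is bisected to 0.1 mm. Bisection predicates are evaluated at a fixed
3000-ray count regardless of the scan's `n_rays`: boundary location demands a
tighter fraction estimate than scanning, and the fixed count keeps refined
boundaries stable (to the 0.1 mm tolerance) when the scan ray count changes.
If several disjoint easy intervals occur, all are reported and the widest is
primary.

The recommended entry height is the −2 mm level (the optimum: the level that
maximises easy access across sides) clamped into the side's easy span, then
lowered by a configurable soft-tissue offset (e.g. 5 mm) to pre-compensate
the upward drift of cheek soft tissues on insertion.

## Härtel's axis

The classical trajectory runs from the trigeminal-impression midpoint
through the FO centre (the aperture centroid) and out through the cheek; its
skin exit is the Einstichpunkt, reported as a signed height. Because the
impression lies beyond the canal along its axis, small elevations of the
axis origin produce several-fold larger depressions of the skin exit (lever
ratio ≈ skin distance / origin depth), reproducing the strong sensitivity of
the Einstichpunkt to the intracranial aiming point.

## Registration

CT↔MRI-style alignment is paired-landmark rigid registration (SVD Kabsch
with determinant correction; no scaling — both frames are metric). The
fiducial registration error (FRE) is the RMS residual; a warning is issued
above 1 mm, matching the ≤1 mm slice-thickness criterion for source imaging.
Rotation recovery depends on the fiducial cloud's lever arm: with six
well-spread points and 0.3 mm noise the median rotation error is ≈0.4°,
with the four clustered petrous-bone stand-ins ≈3.8° — while FRE itself is
lever-arm independent (E[FRE²] = 3σ²(1 − 2/n)).

## Numerical choices

* **Meshing.** Solids are approximate SDFs (exact sign everywhere, metric
  near surfaces); marching cubes at level 0 on a 0.5 mm grid. Sharp rim
  corners are rounded by ≤ half a voxel; dedicated closed-form test phantoms
  use 0.2 mm meshing where corner rounding would otherwise be amplified by
  the entry-to-rim lever arm.
* **Ray casting.** Batched Möller–Trumbore (numba). Per entry point, a
  conservative cone prefilter (apex at the entry, through the rim disc padded
  by each triangle's circumradius plus 1 mm) reduces the bone mesh to the few
  thousand candidate triangles a ray bundle can hit.
* **Rasterization.** Closed meshes are filled by column-crossing parity with
  sub-voxel jittered columns; the open skin sheet becomes a one-voxel shell.
  Voxel grids are cell-centered (origins staggered half a voxel) so solids
  never align degenerately with the lattice. Labels are exclusive with
  precedence bone > cave > skin.
* **Voxel oracle.** The independent cross-check marches rays in 0.25 mm steps
  through labels rasterized directly from the analytic solids (no mesh code
  shared), with trilinearly interpolated occupancy thresholded at 0.5 — the
  standard debiasing that places the effective surface at the half-occupancy
  crossing instead of dilating solids by half a voxel.
* **Degenerate inputs.** Collinear landmark sets, sealed foramina, absent
  labels, floating-point NIfTI volumes, voxels over 1 mm, and entries inside
  bone are all rejected with specific errors. A nearly edge-on aperture
  projection whose convex hull degenerates falls back to principal-axis
  extents for its caliper widths.

## Cohort conditions

The study cohort is 22 sides (11 subjects × 2, alternating mirrored sides),
generated with one cohort seed: canal-axis elevation uniform ±10° about the
40° base, FO semi-axes uniform in 2.6–3.6 × 1.8–2.6 mm, cave semi-axes
jittered ±15%, cave offsets and cheek distance (60–85 mm) jittered. Per-level
hit percentages are aggregated on the common 1 mm grid; both the
easy-or-possible and the easy-only curves are emitted, since "a hit" can be
read either way. Sides with no patent foramen are excluded and reported,
never silently dropped.

Standard problem sizes used throughout the analyses and checks: 0.5 mm
phantom meshing, 1000 aperture rays (fractions converge to <0.02 between 500
and 1000 rays), 1 mm scan grid with 0.1 mm bisection, 0.25 mm oracle
marching, 22-side cohorts.

## Known limitations

* The aperture is measured on a plane normal to the canal axis; real FO
  openings are beveled and their "distinctness" under a given view may
  differ from the prismatic model's.
* The Scene contract assumes one canal per side; `build_aperture` needs the
  canal pose (from phantom ground truth or given explicitly) and does not
  discover foramina in arbitrary label volumes.
* The needle has zero diameter; no collision clearance, bending or tissue
  deformation is modelled.
* Accessible-span widths scale with cheek-sheet extent and are not meant to
  match clinical span statistics numerically; within-phantom structure
  (ordering of regimes, containment of spans, the −2 mm optimum) is the
  meaningful output.
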