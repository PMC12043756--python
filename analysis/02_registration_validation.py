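"""Validate the landmark registration stage on simulated CT/MRI misalignments.

Applies known rigid motions to fiducial sets, jitters the points, re-registers
and reports recovery errors and the fiducial registration error (FRE) as a
function of noise.  Two configurations are compared: the phantom's four
clustered semicircular-canal stand-ins (small lever arm, as in the petrous
bone) and six well-spread points — rotation recovery degrades as the fiducial
cloud shrinks, while FRE itself does not.  Writes
results/registration_validation.csv.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from transoval.phantom import canonical_config, generate_phantom, perturb_scene
from transoval.registration import RigidTransform, fit_rigid

ROOT = Path(__file__).resolve().parents[1]
N_SEEDS = 100


def clustered_rows(T: RigidTransform) -> list[dict]:
    scene = generate_phantom(canonical_config(mesh_voxel_mm=0.7))
    _, src = scene.fiducial_points()
    rows = []
    for noise_sd in (0.0, 0.1, 0.3, 0.5):
        for seed in range(N_SEEDS):
            moved = perturb_scene(scene, T, noise_sd=noise_sd, seed=seed)
            _, tgt = moved.fiducial_points()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = fit_rigid(src, tgt)
            rows.append(_row("clustered_4", noise_sd, seed, src, T, rep))
    return rows


def spread_rows(T: RigidTransform) -> list[dict]:
    rows = []
    for noise_sd in (0.0, 0.1, 0.3, 0.5):
        for seed in range(N_SEEDS):
            rng = np.random.default_rng(seed)
            src = rng.uniform(-40, 40, (6, 3))
            tgt = T.apply(src) + rng.normal(0, noise_sd, src.shape)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = fit_rigid(src, tgt)
            rows.append(_row("spread_6", noise_sd, seed, src, T, rep))
    return rows


def _row(config, noise_sd, seed, src, T, rep) -> dict:
    delta = rep.transform.compose(T.inverse())
    return {
        "fiducials": config,
        "noise_sd_mm": noise_sd,
        "seed": seed,
        "fre_mm": rep.fre_rmse,
        "rotation_error_deg": delta.rotation_angle_deg(),
        "translation_error_mm": float(
            np.linalg.norm(rep.transform.apply(src.mean(0)) - T.apply(src.mean(0)))
        ),
    }


def main() -> None:
    T = RigidTransform.from_rotvec([8.0, -12.0, 20.0], [10.0, -5.0, 8.0])
    df = pd.DataFrame(clustered_rows(T) + spread_rows(T))
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "registration_validation.csv", index=False)
    med = df.groupby(["fiducials", "noise_sd_mm"])[
        ["fre_mm", "rotation_error_deg", "translation_error_mm"]
    ].median().round(4)
    print(med)
    noiseless = df[df.noise_sd_mm == 0.0]
    print(f"\nnoiseless worst rotation error: "
          f"{noiseless.rotation_error_deg.max():.2e} deg (machine precision)")
    m = df[(df.fiducials == "spread_6") & (df.noise_sd_mm == 0.3)]
    print(f"spread 6-point set, 0.3 mm noise: median rotation error "
          f"{m.rotation_error_deg.median():.2f} deg")
    c = df[(df.fiducials == "clustered_4") & (df.noise_sd_mm == 0.3)]
    print(f"clustered 4-point set, 0.3 mm noise: median rotation error "
          f"{c.rotation_error_deg.median():.2f} deg — rotation recovery "
          f"degrades with the fiducial cloud's lever arm, FRE does not.")


if __name__ == "__main__":
    main()
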