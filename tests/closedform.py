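"""Closed-form reference geometry for trajectory-boundary tests.

A deliberately simple phantom — vertical circular canal, spherical cave,
vertical planar cheek, everything mirror-symmetric about the x = 0 plane — so
that the entry-height boundaries of cave visibility are available in closed
form, independent of any ray casting:

* upper traversal bound: the steepest line through both canal rims
  (extracranial anterior edge to intracranial posterior edge) extended to the
  cheek plane;
* lower visibility bound: the line from the entry pivoting on the
  intracranial posterior rim edge becomes tangent to the cave sphere (the
  "cave hides behind the posterior rim" regime);
* slit-like onset: the height at which the orthographically projected rim
  circle narrows below the slit threshold.
"""

from __future__ import annotations

import numpy as np

from transoval import phantom

R_CANAL = 3.0       # circular canal radius (mm)
L_CANAL = 10.0      # canal length (mm)
Y_SKIN = 18.0       # cheek plane y (mm)
Z_MOUTH = -30.0     # mouth-angle height -> heights are z - Z_MOUTH
CAVE_C = np.array([0.0, -11.8, 14.0])
R_CAVE = 5.0
RIM_INSET = 0.3     # must match trajectory.DEFAULT_RIM_INSET_MM


def build_config(mesh_voxel_mm: float = 0.2) -> phantom.PhantomConfig:
    cfg = phantom.PhantomConfig(
        fo_center=[0.0, 0.0, 0.0],
        fo_axis=[0.0, 0.0, 1.0],
        fo_radii=(R_CANAL, R_CANAL),
        cave_center=CAVE_C,
        cave_radii=(R_CAVE, R_CAVE, R_CAVE),
        impression_point=[0.0, -6.0, 12.0],
        mouth_angle=[-8.0, Y_SKIN, Z_MOUTH],
        occlusal_plane_normal=[0.0, 0.0, 1.0],
        fiducials={
            "fiducial_1": [5.0, -25.0, 5.0],
            "fiducial_2": [-5.0, -25.0, 6.0],
            "fiducial_3": [0.0, -30.0, 2.0],
            "fiducial_4": [0.0, -22.0, 9.0],
        },
        ramus_anterior_x=1.0,  # entry line anchored at x = 0
        ramus_enabled=False,
        skin_center=[0.0, Y_SKIN, Z_MOUTH],
        skin_normal=[0.0, 1.0, 0.0],
        mesh_voxel_mm=mesh_voxel_mm,
        plate_half=(15.0, 15.0, 3.0),
        side="right",
    )
    cfg.validate()
    return cfg


def upper_extreme_height() -> float:
    """Entry height of the steepest double-rim-traversing line.

    The line passes (y=+r, z=-L/2) and (y=-r, z=+L/2); above its intersection
    with the cheek plane no straight path threads the canal.
    """
    z = -L_CANAL / 2.0 - (L_CANAL / (2.0 * R_CANAL)) * (Y_SKIN - R_CANAL)
    return z - Z_MOUTH


def lower_extreme_height() -> float:
    """Entry height where the posterior-rim-grazing line is tangent to the cave.

    Below this height the intracranial posterior rim hides the whole cave
    sphere.  Solves |cross(P-E, C-E)| = R_cave * |P-E| for the entry height,
    with P the posterior rim edge (y=-r, z=+L/2), in the x = 0 plane; the
    root whose line actually threads the extracranial rim disc is returned.
    """
    Py, Pz, Ey = -R_CANAL, L_CANAL / 2.0, Y_SKIN
    Cy, Cz = CAVE_C[1], CAVE_C[2]
    c1 = (Cy - Ey) - (Py - Ey)
    c0 = (Py - Ey) * Cz - Pz * (Cy - Ey)
    a2 = c1**2 - R_CAVE**2
    a1 = 2 * c1 * c0 + 2 * R_CAVE**2 * Pz
    a0 = c0**2 - R_CAVE**2 * ((Py - Ey) ** 2 + Pz**2)
    roots = np.sort(np.real(np.roots([a2, a1, a0])))
    for z in roots:
        y_bottom = Ey + (Py - Ey) * (-L_CANAL / 2.0 - z) / (Pz - z)
        if abs(y_bottom) < R_CANAL:
            return float(z - Z_MOUTH)
    raise RuntimeError("no valid tangency root; geometry misconfigured")


def slit_onset_height(slit_threshold: float = 2.0) -> float:
    """Entry height above which the projected rim is narrower than the threshold.

    The rim circle (radius r, in the plane z = -(L/2) + inset) projects, along
    the entry->centroid direction, to an ellipse of minor width 2 r cos(alpha)
    with alpha the view angle off the canal axis.
    """
    z_rim = -(L_CANAL / 2.0 - RIM_INSET)
    k = slit_threshold / (2.0 * R_CANAL)
    q = Y_SKIN * k / np.sqrt(1.0 - k * k)
    return (z_rim - q) - Z_MOUTH


def analytic_einstich_height(cfg: phantom.PhantomConfig, inset: float = RIM_INSET) -> float:
    """Härtel-axis exit height by pure line-plane intersection.

    Uses the analytic rim-disc centre (no meshes): the line from the
    impression point through it, intersected with the configured cheek plane;
    height measured against the occlusal normal through the mouth angle.
    """
    centroid = cfg.fo_center - (cfg.fo_canal_length / 2.0 - inset) * cfg.fo_axis
    origin = cfg.impression_point
    d = centroid - origin
    p0, n = cfg.skin_plane()
    t = np.dot(p0 - origin, n) / np.dot(d, n)
    exit_point = origin + t * d
    n_h = cfg.occlusal_plane_normal
    return float(np.dot(exit_point - cfg.mouth_angle, n_h))
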