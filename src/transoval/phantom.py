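"""Parametric skull-base phantom: foramen ovale canal, Meckel's cave, mandibular
ramus occluder, cheek sheet and landmarks.

The phantom stands in for coregistered CT/MRI of a real head.  Its elements:

* a horizontal bone plate (the planum infratemporale / middle-fossa floor)
  pierced obliquely by an elliptical bony canal ~1 cm long (the foramen ovale,
  which is a canal in the sphenoid rather than a simple hole);
* a short bony collar around the canal so the canal has well-defined
  extracranial and intracranial rims;
* an ellipsoidal Meckel's cave posterosuperior to the intracranial canal exit;
* a vertical bone slab lateral to the corridor (the anterior part of the
  mandibular ramus), which occludes overly lateral entry points;
* an open planar cheek sheet, the mouth angle, occlusal (bite-plane) points,
  the trigeminal-impression midpoint, and >=3 skull-base fiducials standing in
  for the semicircular-canal registration points.

All solids are defined as approximate signed-distance fields and surfaced with
marching cubes, which guarantees watertight meshes at a controllable
resolution.  Geometry is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
import yaml
from numba import njit
from skimage import measure

from . import imaging
from .frames import HorizontalPlane, make_horizontal_plane
from .raycast import TriangleSet, points_in_mesh


class ConfigurationError(ValueError):
    """Invalid phantom configuration; the message names the offending field."""


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PhantomConfig:
    """Ground-truth geometry of one side's phantom (all lengths in mm, RAS).

    The canonical values produced by :func:`canonical_config` model a right
    side with the canal axis pointing intracranially (up, posteriorly and
    slightly medially); left sides are mirrored across the mid-sagittal plane.
    """

    fo_center: np.ndarray
    fo_axis: np.ndarray
    fo_radii: tuple[float, float]  # (medial-lateral, antero-posterior) semi-axes
    cave_center: np.ndarray
    cave_radii: tuple[float, float, float]
    impression_point: np.ndarray
    mouth_angle: np.ndarray
    occlusal_plane_normal: np.ndarray
    fiducials: dict[str, np.ndarray]
    fo_canal_length: float = 10.0
    skin_offset: float = 70.0
    ramus_anterior_x: float = 35.0
    ramus_enabled: bool = True
    skin_center: np.ndarray | None = None
    skin_normal: np.ndarray | None = None
    noise_sd: float = 0.0
    seed: int = 0
    side: str = "right"
    # construction knobs
    mesh_voxel_mm: float = 0.5
    plate_half: tuple[float, float, float] = (40.0, 40.0, 3.0)
    collar_wall_mm: float = 2.5
    canal_cut_margin_mm: float = 3.0
    ramus_thickness: float = 7.0
    ramus_y: tuple[float, float] = (5.0, 50.0)
    ramus_z: tuple[float, float] = (-55.0, -4.0)
    skin_size: float = 170.0
    skin_step: float = 2.0
    occlusal_ring_radius: float = 14.0
    n_occlusal: int = 8
    planar_fiducials: bool = False
    canonical_frame: bool = True  # False after rigid transforms: implicit solids invalid

    def __post_init__(self):
        for name in ("fo_center", "cave_center", "impression_point", "mouth_angle"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        self.fo_axis = np.asarray(self.fo_axis, dtype=float).reshape(3)
        self.occlusal_plane_normal = np.asarray(
            self.occlusal_plane_normal, dtype=float
        ).reshape(3)
        if self.skin_center is not None:
            self.skin_center = np.asarray(self.skin_center, dtype=float).reshape(3)
        if self.skin_normal is not None:
            self.skin_normal = np.asarray(self.skin_normal, dtype=float).reshape(3)
        self.fiducials = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.fiducials.items()}
        self.fo_radii = tuple(float(v) for v in self.fo_radii)
        self.cave_radii = tuple(float(v) for v in self.cave_radii)

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if not self.fo_canal_length > 0:
            raise ConfigurationError(f"fo_canal_length must be > 0, got {self.fo_canal_length}")
        if not all(r > 0 for r in self.fo_radii):
            raise ConfigurationError(f"fo_radii must be > 0, got {self.fo_radii}")
        if not all(r > 0 for r in self.cave_radii):
            raise ConfigurationError(f"cave_radii must be > 0, got {self.cave_radii}")
        if abs(np.linalg.norm(self.fo_axis) - 1.0) > 1e-9:
            raise ConfigurationError("fo_axis must have unit norm")
        if abs(np.linalg.norm(self.occlusal_plane_normal) - 1.0) > 1e-9:
            raise ConfigurationError("occlusal_plane_normal must have unit norm")
        exit_extracranial = self.fo_center - 0.5 * self.fo_canal_length * self.fo_axis
        if np.dot(self.cave_center - exit_extracranial, self.fo_axis) <= 0:
            raise ConfigurationError(
                "cave_center lies on the extracranial side of the FO exit plane"
            )
        if len(self.fiducials) < 3:
            raise ConfigurationError("fiducials: need at least 3 points")
        F = np.array(list(self.fiducials.values()))
        sv = np.linalg.svd(F - F.mean(axis=0), compute_uv=False)
        rank = int(np.sum(sv > 1e-9 * max(sv[0], 1.0)))
        if rank < 2:
            raise ConfigurationError("fiducials are collinear")
        if rank == 2 and not self.planar_fiducials:
            raise ConfigurationError(
                "fiducials are coplanar; set planar_fiducials=True to accept"
            )
        if self.side not in ("right", "left"):
            raise ConfigurationError(f"side must be 'right' or 'left', got {self.side!r}")

    # -- derived geometry ---------------------------------------------------

    @property
    def lateral_sign(self) -> float:
        return 1.0 if self.side == "right" else -1.0

    @property
    def extracranial_exit(self) -> np.ndarray:
        """Centre of the extracranial canal rim (where the needle enters bone)."""
        return self.fo_center - 0.5 * self.fo_canal_length * self.fo_axis

    @property
    def intracranial_exit(self) -> np.ndarray:
        return self.fo_center + 0.5 * self.fo_canal_length * self.fo_axis

    @property
    def entry_anchor_x(self) -> float:
        """Lateral anchor of the tested entry line: 1 mm in front of the ramus face."""
        return self.ramus_anterior_x - self.lateral_sign * 1.0

    def canal_frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (u, v, axis) with u the in-aperture medial-lateral axis."""
        a = self.fo_axis
        u = np.array([1.0, 0.0, 0.0]) - np.dot([1.0, 0.0, 0.0], a) * a
        if np.linalg.norm(u) < 1e-6:
            u = np.array([0.0, 1.0, 0.0]) - np.dot([0.0, 1.0, 0.0], a) * a
        u = _unit(u)
        v = np.cross(a, u)
        return u, v, a

    def skin_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """(center, outward unit normal) of the cheek sheet."""
        if self.skin_center is not None:
            center = self.skin_center
        else:
            center = self.extracranial_exit - self.skin_offset * self.fo_axis
        if self.skin_normal is not None:
            normal = _unit(self.skin_normal)
        else:
            normal = _unit(np.array([self.lateral_sign * 0.42, 0.88, 0.22]))
        return center, normal

    def ramus_box(self) -> tuple[np.ndarray, np.ndarray] | None:
        """(center, half-extents) of the ramus slab, or None when disabled."""
        if not self.ramus_enabled:
            return None
        x0 = self.ramus_anterior_x
        x1 = self.ramus_anterior_x + self.lateral_sign * self.ramus_thickness
        lo = np.array([min(x0, x1), self.ramus_y[0], self.ramus_z[0]])
        hi = np.array([max(x0, x1), self.ramus_y[1], self.ramus_z[1]])
        return (lo + hi) / 2.0, (hi - lo) / 2.0

    def transformed(self, transform) -> "PhantomConfig":
        """Map every world point/direction by a rigid motion.

        The result keeps ground-truth canal pose usable (centre, axis, length)
        but is flagged non-canonical: axis-aligned implicit solids (plate,
        ramus box) are no longer valid in the new frame.
        """
        R = transform.rotation
        skin_c, skin_n = self.skin_plane()
        return replace(
            self,
            fo_center=transform.apply(self.fo_center),
            fo_axis=R @ self.fo_axis,
            cave_center=transform.apply(self.cave_center),
            impression_point=transform.apply(self.impression_point),
            mouth_angle=transform.apply(self.mouth_angle),
            occlusal_plane_normal=R @ self.occlusal_plane_normal,
            fiducials={k: transform.apply(v) for k, v in self.fiducials.items()},
            skin_center=transform.apply(skin_c),
            skin_normal=R @ skin_n,
            canonical_frame=False,
        )

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = [float(x) for x in v]
            elif isinstance(v, dict):
                v = {k: [float(x) for x in p] for k, p in v.items()}
            elif isinstance(v, tuple):
                v = [float(x) for x in v]
            elif isinstance(v, np.generic):
                v = v.item()
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for name in ("fo_radii", "cave_radii", "plate_half", "ramus_y", "ramus_z"):
            if name in d and d[name] is not None:
                d[name] = tuple(d[name])
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "PhantomConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))


def canonical_config(
    side: str = "right",
    seed: int = 0,
    elevation_deg: float = 40.0,
    medial_tilt: float = 0.12,
    fo_radii: tuple[float, float] = (3.2, 2.2),
    cave_radii: tuple[float, float, float] = (5.0, 8.0, 4.5),
    skin_offset: float = 70.0,
    cave_posterior_offset: float = -8.0,
    cave_superior_offset: float = 3.0,
    cave_medial_offset: float = 3.0,
    **overrides,
) -> PhantomConfig:
    """Literature-plausible default phantom for one side.

    ``elevation_deg`` is the canal axis' elevation above the horizontal plane;
    the axis points intracranially (up, posteriorly, slightly medially), so the
    needle travels up-posterior-medial from the cheek, as in the transoval
    route.  FO aperture semi-axes default to 3.2 x 2.2 mm and the canal to
    10 mm length; the cave is an 8 x 5.5 x 4.5 mm semi-axis ellipsoid
    posterosuperior to the intracranial exit.
    """
    s = 1.0 if side == "right" else -1.0
    e = np.radians(elevation_deg)
    axis = _unit(np.array([-s * medial_tilt, -np.cos(e), np.sin(e)]))
    fo_center = np.array([s * 25.0, 0.0, 0.0])
    L = float(overrides.get("fo_canal_length", 10.0))
    exit_extra = fo_center - 0.5 * L * axis
    skin_center = exit_extra - skin_offset * axis
    skin_normal = _unit(np.array([s * 0.42, 0.88, 0.22]))
    # mouth angle ~30 mm anteromedial of the optimal entry, 2 mm above it,
    # so that the axis-aligned entry sits at the -2 mm archetype height
    d_m = np.array([-s * 0.8, 0.6, 0.0])
    u_m = _unit(d_m - np.dot(d_m, skin_normal) * skin_normal)
    mouth = skin_center + 30.0 * u_m
    mouth[2] = skin_center[2] + 2.0
    cave_center = fo_center + (0.5 * L + 8.0) * axis + np.array(
        [-s * cave_medial_offset, cave_posterior_offset, cave_superior_offset]
    )
    # the trigeminal impression sits on the petrous bone roughly on the
    # intracranial extension of the canal axis (which is why Härtel's axis is
    # nearly coaxial with the canal), just deep to the cave
    impression = fo_center + (0.5 * L + 5.0) * axis + np.array([0.0, -1.0, -0.5])
    fiducials = {
        "fiducial_1": fo_center + np.array([s * 20.0, -22.0, 4.0]),
        "fiducial_2": fo_center + np.array([s * 14.0, -26.0, 2.0]),
        "fiducial_3": fo_center + np.array([s * 22.0, -28.0, 0.0]),
        "fiducial_4": fo_center + np.array([s * 17.0, -24.0, 7.0]),
    }
    ramus_x = s * (abs(skin_center[0]) + 1.0)
    cfg = PhantomConfig(
        fo_center=fo_center,
        fo_axis=axis,
        fo_radii=fo_radii,
        cave_center=cave_center,
        cave_radii=cave_radii,
        impression_point=impression,
        mouth_angle=mouth,
        occlusal_plane_normal=np.array([0.0, 0.0, 1.0]),
        fiducials=fiducials,
        skin_offset=skin_offset,
        ramus_anterior_x=ramus_x,
        skin_center=skin_center,
        skin_normal=skin_normal,
        seed=seed,
        side=side,
    )
    for k, v in overrides.items():
        cfg = replace(cfg, **{k: v})
    cfg.validate()
    return cfg


def sample_cohort_configs(
    n_sides: int,
    seed: int,
    base_elevation_deg: float = 40.0,
    elevation_jitter_deg: float = 10.0,
) -> list[PhantomConfig]:
    """Draw a cohort of per-side phantoms with inter-individual variation.

    Canal-axis elevation is uniform +-``elevation_jitter_deg`` about the base;
    FO aperture radii, cave size/position and cheek offset receive mild
    independent jitter.  Sides alternate right/left (mirrored geometry), as in
    a cohort of bilateral measurements.
    """
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(n_sides):
        side = "right" if i % 2 == 0 else "left"
        elev = base_elevation_deg + rng.uniform(-elevation_jitter_deg, elevation_jitter_deg)
        fo_r = (rng.uniform(2.6, 3.6), rng.uniform(1.8, 2.6))
        cave_r = tuple(np.array([5.0, 8.0, 4.5]) * rng.uniform(0.85, 1.15, size=3))
        cfg = canonical_config(
            side=side,
            seed=int(rng.integers(0, 2**31 - 1)),
            elevation_deg=elev,
            fo_radii=fo_r,
            cave_radii=cave_r,
            skin_offset=rng.uniform(60.0, 85.0),
            cave_posterior_offset=rng.uniform(-9.5, -6.5),
            cave_superior_offset=rng.uniform(2.0, 4.0),
            cave_medial_offset=rng.uniform(2.0, 4.0),
        )
        configs.append(cfg)
    return configs


# ---------------------------------------------------------------------------
# implicit solids (approximate signed distances; exact sign everywhere)


def _box_sdf(p: np.ndarray, center: np.ndarray, half: np.ndarray) -> np.ndarray:
    q = np.abs(p - center) - np.asarray(half)
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
    inside = np.minimum(np.max(q, axis=-1), 0.0)
    return outside + inside


def _ellipse_sdf(cu: np.ndarray, cv: np.ndarray, a: float, b: float) -> np.ndarray:
    """Approximate signed distance to an elliptical cylinder cross-section."""
    q = np.sqrt((cu / a) ** 2 + (cv / b) ** 2)
    grad = np.sqrt((cu / a**2) ** 2 + (cv / b**2) ** 2)
    safe = grad > 1e-12
    d = np.where(safe, (q - 1.0) * np.where(safe, q, 1.0) / np.where(safe, grad, 1.0), -min(a, b))
    return d


def bone_sdf(cfg: PhantomConfig, pts: np.ndarray) -> np.ndarray:
    """Approximate signed distance to the bone solid (negative inside).

    Bone = (plate U canal collar U ramus slab) minus the canal interior.
    Only valid while the config is in its canonical (axis-aligned) frame.
    """
    if not cfg.canonical_frame:
        raise ValueError("implicit bone solid is only defined in the canonical frame")
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    u, v, a = cfg.canal_frame()
    rel = pts - cfg.fo_center
    s = rel @ a
    cu = rel @ u
    cv = rel @ v
    ra, rb = cfg.fo_radii
    w = cfg.collar_wall_mm
    L2 = cfg.fo_canal_length / 2.0
    d_canal = np.maximum(
        _ellipse_sdf(cu, cv, ra, rb), np.abs(s) - (L2 + cfg.canal_cut_margin_mm)
    )
    d_collar = np.maximum(_ellipse_sdf(cu, cv, ra + w, rb + w), np.abs(s) - L2)
    plate_center = np.array([cfg.fo_center[0], cfg.fo_center[1], cfg.fo_center[2]])
    d_solid = np.minimum(_box_sdf(pts, plate_center, np.asarray(cfg.plate_half)), d_collar)
    box = cfg.ramus_box()
    if box is not None:
        d_solid = np.minimum(d_solid, _box_sdf(pts, box[0], box[1]))
    return np.maximum(d_solid, -d_canal)


@njit(cache=True, fastmath=True)
def _sdf_point(
    x, y, z,
    plate_c, plate_h, has_ramus, ramus_c, ramus_h,
    fo_c, u, v, a, ra, rb, w, L2, cut,
):
    # plate box
    qx = abs(x - plate_c[0]) - plate_h[0]
    qy = abs(y - plate_c[1]) - plate_h[1]
    qz = abs(z - plate_c[2]) - plate_h[2]
    ox = qx if qx > 0.0 else 0.0
    oy = qy if qy > 0.0 else 0.0
    oz = qz if qz > 0.0 else 0.0
    mx = qx if qx > qy else qy
    mx = mx if mx > qz else qz
    d_solid = np.sqrt(ox * ox + oy * oy + oz * oz) + (mx if mx < 0.0 else 0.0)
    if has_ramus:
        qx = abs(x - ramus_c[0]) - ramus_h[0]
        qy = abs(y - ramus_c[1]) - ramus_h[1]
        qz = abs(z - ramus_c[2]) - ramus_h[2]
        ox = qx if qx > 0.0 else 0.0
        oy = qy if qy > 0.0 else 0.0
        oz = qz if qz > 0.0 else 0.0
        mx = qx if qx > qy else qy
        mx = mx if mx > qz else qz
        d_r = np.sqrt(ox * ox + oy * oy + oz * oz) + (mx if mx < 0.0 else 0.0)
        if d_r < d_solid:
            d_solid = d_r
    rx = x - fo_c[0]
    ry = y - fo_c[1]
    rz = z - fo_c[2]
    s = rx * a[0] + ry * a[1] + rz * a[2]
    cu = rx * u[0] + ry * u[1] + rz * u[2]
    cv = rx * v[0] + ry * v[1] + rz * v[2]
    # collar (outer elliptical cylinder, |s| <= L2)
    ro_a = ra + w
    ro_b = rb + w
    q = np.sqrt((cu / ro_a) ** 2 + (cv / ro_b) ** 2)
    g = np.sqrt((cu / ro_a**2) ** 2 + (cv / ro_b**2) ** 2)
    d_out = (q - 1.0) * q / g if g > 1e-12 else -(ro_a if ro_a < ro_b else ro_b)
    d_cap = abs(s) - L2
    d_collar = d_out if d_out > d_cap else d_cap
    if d_collar < d_solid:
        d_solid = d_collar
    # canal interior
    q = np.sqrt((cu / ra) ** 2 + (cv / rb) ** 2)
    g = np.sqrt((cu / ra**2) ** 2 + (cv / rb**2) ** 2)
    d_in = (q - 1.0) * q / g if g > 1e-12 else -(ra if ra < rb else rb)
    d_cut = abs(s) - (L2 + cut)
    d_canal = d_in if d_in > d_cut else d_cut
    neg = -d_canal
    return d_solid if d_solid > neg else neg


@njit(cache=True, fastmath=True)
def _bone_sdf_grid(
    lo, h, shape,
    plate_c, plate_h, has_ramus, ramus_c, ramus_h,
    fo_c, u, v, a, ra, rb, w, L2, cut,
):
    out = np.empty((shape[0], shape[1], shape[2]), dtype=np.float32)
    for ix in range(shape[0]):
        x = lo[0] + h * ix
        for iy in range(shape[1]):
            y = lo[1] + h * iy
            for iz in range(shape[2]):
                z = lo[2] + h * iz
                out[ix, iy, iz] = _sdf_point(
                    x, y, z, plate_c, plate_h, has_ramus, ramus_c, ramus_h,
                    fo_c, u, v, a, ra, rb, w, L2, cut,
                )
    return out


@njit(cache=True, fastmath=True)
def _label_grid(
    lo, h, shape,
    plate_c, plate_h, has_ramus, ramus_c, ramus_h,
    fo_c, u, v, a, ra, rb, w, L2, cut,
    cave_c, cave_r,
):
    out = np.zeros((shape[0], shape[1], shape[2]), dtype=np.int16)
    for ix in range(shape[0]):
        x = lo[0] + h * ix
        for iy in range(shape[1]):
            y = lo[1] + h * iy
            for iz in range(shape[2]):
                z = lo[2] + h * iz
                d = _sdf_point(
                    x, y, z, plate_c, plate_h, has_ramus, ramus_c, ramus_h,
                    fo_c, u, v, a, ra, rb, w, L2, cut,
                )
                if d <= 0.0:
                    out[ix, iy, iz] = 1
                else:
                    e = (
                        ((x - cave_c[0]) / cave_r[0]) ** 2
                        + ((y - cave_c[1]) / cave_r[1]) ** 2
                        + ((z - cave_c[2]) / cave_r[2]) ** 2
                    )
                    if e <= 1.0:
                        out[ix, iy, iz] = 2
    return out


def _kernel_args(cfg: PhantomConfig):
    u, v, a = cfg.canal_frame()
    box = cfg.ramus_box()
    has_ramus = box is not None
    ramus_c = box[0] if has_ramus else np.zeros(3)
    ramus_h = box[1] if has_ramus else np.zeros(3)
    return (
        cfg.fo_center.astype(np.float64),
        np.asarray(cfg.plate_half, dtype=np.float64),
        has_ramus,
        ramus_c.astype(np.float64),
        ramus_h.astype(np.float64),
        cfg.fo_center.astype(np.float64),
        u, v, a,
        float(cfg.fo_radii[0]), float(cfg.fo_radii[1]),
        float(cfg.collar_wall_mm),
        cfg.fo_canal_length / 2.0,
        float(cfg.canal_cut_margin_mm),
    )


def cave_sdf(cfg: PhantomConfig, pts: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    rel = pts - cfg.cave_center
    r = np.asarray(cfg.cave_radii)
    q = np.sqrt(np.sum((rel / r) ** 2, axis=-1))
    grad = np.sqrt(np.sum((rel / r**2) ** 2, axis=-1))
    safe = grad > 1e-12
    return np.where(safe, (q - 1.0) * np.where(safe, q, 1.0) / np.where(safe, grad, 1.0), -min(r))


# ---------------------------------------------------------------------------
# scene


@dataclass
class Scene:
    """One side's anatomy: meshes + landmarks + measurement frame."""

    bone_mesh: trimesh.Trimesh
    cave_mesh: trimesh.Trimesh
    skin_mesh: trimesh.Trimesh
    landmarks: dict[str, np.ndarray]
    horizontal_plane: HorizontalPlane
    side: str
    ground_truth: PhantomConfig | None = None

    REQUIRED_LANDMARKS = ("mouth_angle", "impression_point")

    def validate(self, check_intersection: bool = True) -> None:
        for name in self.REQUIRED_LANDMARKS:
            if name not in self.landmarks:
                raise ValueError(f"required landmark missing: {name}")
        n_fid = sum(1 for k in self.landmarks if k.startswith("fiducial"))
        if n_fid < 3:
            raise ValueError(f"need >=3 fiducial landmarks, found {n_fid}")
        for label, mesh in (("bone", self.bone_mesh), ("cave", self.cave_mesh)):
            if mesh is not None and len(mesh.faces) and not mesh.is_watertight:
                raise ValueError(f"{label} mesh is not watertight")
        if check_intersection and self.bone_mesh is not None and self.cave_mesh is not None:
            if self.ground_truth is not None and self.ground_truth.canonical_frame:
                d = bone_sdf(self.ground_truth, self.cave_mesh.vertices)
                inside = d <= 0
            else:
                inside = points_in_mesh(
                    self.cave_mesh.vertices, np.asarray(self.bone_mesh.triangles)
                )
            if np.any(inside):
                raise ValueError("cave mesh intersects bone")

    def fiducial_points(self) -> tuple[list[str], np.ndarray]:
        names = sorted(k for k in self.landmarks if k.startswith("fiducial"))
        return names, np.array([self.landmarks[k] for k in names])

    def occlusal_points(self) -> np.ndarray:
        names = sorted(k for k in self.landmarks if k.startswith("occlusal"))
        return np.array([self.landmarks[k] for k in names])

    def transformed(self, transform) -> "Scene":
        def tmesh(m):
            if m is None:
                return None
            out = m.copy()
            out.apply_transform(transform.matrix)
            return out

        return Scene(
            bone_mesh=tmesh(self.bone_mesh),
            cave_mesh=tmesh(self.cave_mesh),
            skin_mesh=tmesh(self.skin_mesh),
            landmarks={k: transform.apply(v) for k, v in self.landmarks.items()},
            horizontal_plane=self.horizontal_plane.transformed(transform),
            side=self.side,
            ground_truth=None
            if self.ground_truth is None
            else self.ground_truth.transformed(transform),
        )


def _sheet_mesh(center: np.ndarray, normal: np.ndarray, size: float, step: float) -> trimesh.Trimesh:
    """An open rectangular sheet (two triangles per grid cell)."""
    n = _unit(normal)
    e1 = np.array([0.0, 0.0, 1.0]) - n[2] * n
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.array([1.0, 0.0, 0.0]) - n[0] * n
    e1 = _unit(e1)
    e2 = np.cross(n, e1)
    k = int(round(size / step))
    coords = (np.arange(k + 1) - k / 2.0) * step
    verts = (
        center[None, None, :]
        + coords[:, None, None] * e1[None, None, :]
        + coords[None, :, None] * e2[None, None, :]
    ).reshape(-1, 3)
    faces = []
    for i in range(k):
        for j in range(k):
            a = i * (k + 1) + j
            b = a + 1
            c = a + (k + 1)
            d = c + 1
            faces.append([a, c, b])
            faces.append([b, c, d])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def mirror_config(cfg: PhantomConfig) -> PhantomConfig:
    """The contralateral twin: every point/direction reflected across x = 0."""

    def mp(p):
        q = np.asarray(p, dtype=float).copy()
        q[0] = -q[0]
        return q

    skin_c = None if cfg.skin_center is None else mp(cfg.skin_center)
    skin_n = None if cfg.skin_normal is None else mp(cfg.skin_normal)
    return replace(
        cfg,
        fo_center=mp(cfg.fo_center),
        fo_axis=mp(cfg.fo_axis),
        cave_center=mp(cfg.cave_center),
        impression_point=mp(cfg.impression_point),
        mouth_angle=mp(cfg.mouth_angle),
        occlusal_plane_normal=mp(cfg.occlusal_plane_normal),
        fiducials={k: mp(v) for k, v in cfg.fiducials.items()},
        skin_center=skin_c,
        skin_normal=skin_n,
        ramus_anterior_x=-cfg.ramus_anterior_x,
        side="left" if cfg.side == "right" else "right",
    )


def _mirror_mesh(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    v = mesh.vertices.copy()
    v[:, 0] = -v[:, 0]
    # reverse winding to keep outward orientation after the reflection
    return trimesh.Trimesh(vertices=v, faces=mesh.faces[:, ::-1], process=False)


def _mirror_point(p: np.ndarray) -> np.ndarray:
    q = np.asarray(p, dtype=float).copy()
    q[0] = -q[0]
    return q


def generate_phantom(config: PhantomConfig) -> Scene:
    """Build the meshes, landmarks and measurement frame for one side.

    Deterministic: identical config (including seed) gives bit-identical
    vertex arrays.  Left sides are generated as the exact mirror image of
    their right-handed twin, so left/right pairs are bit-symmetric.
    """
    config.validate()
    if not config.canonical_frame:
        raise ConfigurationError("canonical_frame: cannot generate from a transformed config")
    if config.side == "left":
        twin = generate_phantom(mirror_config(config))
        return Scene(
            bone_mesh=_mirror_mesh(twin.bone_mesh),
            cave_mesh=_mirror_mesh(twin.cave_mesh),
            skin_mesh=_mirror_mesh(twin.skin_mesh),
            landmarks={k: _mirror_point(v) for k, v in twin.landmarks.items()},
            horizontal_plane=HorizontalPlane(
                _mirror_point(twin.horizontal_plane.origin),
                _mirror_point(twin.horizontal_plane.normal),
            ),
            side="left",
            ground_truth=config,
        )
    h = config.mesh_voxel_mm

    # bounding box of all bone solids
    ra, rb = config.fo_radii
    pad = config.fo_canal_length / 2.0 + ra + rb + config.collar_wall_mm + 2.0
    lows = [config.fo_center - config.plate_half - 0, config.fo_center - pad]
    highs = [config.fo_center + np.asarray(config.plate_half), config.fo_center + pad]
    box = config.ramus_box()
    if box is not None:
        lows.append(box[0] - box[1])
        highs.append(box[0] + box[1])
    lo = np.min(lows, axis=0) - 2.0
    hi = np.max(highs, axis=0) + 2.0

    shape = np.ceil((hi - lo) / h).astype(int) + 1
    sdf = _bone_sdf_grid(lo, h, shape, *_kernel_args(config))
    verts, faces, _, _ = measure.marching_cubes(sdf, level=0.0, spacing=(h, h, h))
    verts = verts + lo
    bone = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if bone.volume < 0:
        bone.invert()

    cave = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    cave.apply_scale(np.asarray(config.cave_radii))
    cave.apply_translation(config.cave_center)

    skin_center, skin_normal = config.skin_plane()
    skin = _sheet_mesh(skin_center, skin_normal, config.skin_size, config.skin_step)

    rng = np.random.default_rng(config.seed)
    # occlusal ring: points on the bite plane around the mouth region
    n_occ = config.n_occlusal
    occ_n = _unit(config.occlusal_plane_normal)
    o1 = np.array([1.0, 0.0, 0.0]) - occ_n[0] * occ_n
    o1 = _unit(o1)
    o2 = np.cross(occ_n, o1)
    angles = 2 * np.pi * np.arange(n_occ) / n_occ
    ring_center = config.mouth_angle + 10.0 * o2 * np.sign(np.dot(o2, [0, 1, 0]) or 1.0)
    occ_pts = (
        ring_center[None, :]
        + config.occlusal_ring_radius * np.cos(angles)[:, None] * o1[None, :]
        + config.occlusal_ring_radius * np.sin(angles)[:, None] * o2[None, :]
    )
    if config.noise_sd > 0:
        occ_pts = occ_pts + rng.normal(0.0, config.noise_sd, size=occ_pts.shape)

    landmarks: dict[str, np.ndarray] = {
        "mouth_angle": config.mouth_angle.copy(),
        "impression_point": config.impression_point.copy(),
    }
    # entry-line anchor: on the cheek sheet, 1 mm in front of the ramus face,
    # at height 0 (the horizontal plane through the mouth angle)
    occ_n_unit = _unit(config.occlusal_plane_normal)
    A = np.stack([skin_normal, np.array([1.0, 0.0, 0.0]), occ_n_unit])
    b = np.array(
        [
            float(np.dot(skin_normal, skin_center)),
            config.entry_anchor_x,
            float(np.dot(occ_n_unit, config.mouth_angle)),
        ]
    )
    if abs(np.linalg.det(A)) > 1e-9:
        landmarks["entry_anchor"] = np.linalg.solve(A, b)
    for name, p in config.fiducials.items():
        landmarks[name] = p.copy()
    for i, p in enumerate(occ_pts, start=1):
        landmarks[f"occlusal_{i}"] = p

    _, fid_pts = (
        sorted(config.fiducials),
        np.array([config.fiducials[k] for k in sorted(config.fiducials)]),
    )
    plane = make_horizontal_plane(
        config.mouth_angle, occ_pts, cranial_reference=fid_pts.mean(axis=0)
    )
    scene = Scene(
        bone_mesh=bone,
        cave_mesh=cave,
        skin_mesh=skin,
        landmarks=landmarks,
        horizontal_plane=plane,
        side=config.side,
        ground_truth=config,
    )
    return scene


def perturb_scene(scene: Scene, transform, noise_sd: float = 0.0, seed: int = 0) -> Scene:
    """Rigidly move a scene and jitter its fiducials (emulating an MRI frame).

    Fiducial landmarks receive isotropic Gaussian noise of sd ``noise_sd`` mm;
    everything else is mapped exactly.  Deterministic per seed.
    """
    out = scene.transformed(transform)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for k in sorted(out.landmarks):
            if k.startswith("fiducial"):
                out.landmarks[k] = out.landmarks[k] + rng.normal(0.0, noise_sd, size=3)
    return out


# ---------------------------------------------------------------------------
# rasterization


@njit(cache=True)
def _bin_count(tri_ix0, tri_ix1, tri_iy0, tri_iy1, nx, ny):
    counts = np.zeros(nx * ny + 1, dtype=np.int64)
    for t in range(tri_ix0.shape[0]):
        for ix in range(tri_ix0[t], tri_ix1[t] + 1):
            for iy in range(tri_iy0[t], tri_iy1[t] + 1):
                counts[ix * ny + iy + 1] += 1
    return counts


@njit(cache=True)
def _bin_fill(tri_ix0, tri_ix1, tri_iy0, tri_iy1, ny, starts):
    cursor = starts[:-1].copy()
    items = np.empty(starts[-1], dtype=np.int64)
    for t in range(tri_ix0.shape[0]):
        for ix in range(tri_ix0[t], tri_ix1[t] + 1):
            for iy in range(tri_iy0[t], tri_iy1[t] + 1):
                c = ix * ny + iy
                items[cursor[c]] = t
                cursor[c] += 1
    return items


@njit(cache=True)
def _fill_parity(tris, starts, items, nx, ny, nz, x0, y0, z0, h, label, out):
    """Column-parity solid fill of a closed mesh into an integer grid."""
    max_cross = 128
    ts = np.empty(max_cross, dtype=np.float64)
    jx = 0.31234e-3  # sub-voxel jitter avoids hitting edges/vertices exactly
    jy = 0.52718e-3
    for ix in range(nx):
        for iy in range(ny):
            c = ix * ny + iy
            s0, s1 = starts[c], starts[c + 1]
            if s0 == s1:
                continue
            ox = x0 + ix * h + jx
            oy = y0 + iy * h + jy
            oz = z0 - 1.0
            n = 0
            for k in range(s0, s1):
                j = items[k]
                ax, ay, az = tris[j, 0, 0], tris[j, 0, 1], tris[j, 0, 2]
                e1x = tris[j, 1, 0] - ax
                e1y = tris[j, 1, 1] - ay
                e1z = tris[j, 1, 2] - az
                e2x = tris[j, 2, 0] - ax
                e2y = tris[j, 2, 1] - ay
                e2z = tris[j, 2, 2] - az
                # dir = (0,0,1):  p = d x e2 = (-e2y, e2x, 0)
                px = -e2y
                py = e2x
                det = e1x * px + e1y * py
                if -1e-12 < det < 1e-12:
                    continue
                inv = 1.0 / det
                tx = ox - ax
                ty = oy - ay
                tz = oz - az
                u = (tx * px + ty * py) * inv
                if u < 0.0 or u > 1.0:
                    continue
                qx = ty * e1z - tz * e1y
                qy = tz * e1x - tx * e1z
                qz = tx * e1y - ty * e1x
                v = qz * inv
                if v < 0.0 or u + v > 1.0:
                    continue
                t = (e2x * qx + e2y * qy + e2z * qz) * inv
                if n < max_cross:
                    ts[n] = t
                    n += 1
            if n < 2:
                continue
            sub = ts[:n]
            sub.sort()
            m = n - (n % 2)
            for p in range(0, m, 2):
                ta, tb = sub[p], sub[p + 1]
                iz0 = int(np.ceil((ta - 1.0) / h + 1e-9))
                iz1 = int(np.floor((tb - 1.0) / h - 1e-9))
                if iz0 < 0:
                    iz0 = 0
                if iz1 > nz - 1:
                    iz1 = nz - 1
                for iz in range(iz0, iz1 + 1):
                    if out[ix, iy, iz] == 0:
                        out[ix, iy, iz] = label


def _fill_mesh(mesh: trimesh.Trimesh, out, lo, h, label) -> None:
    tris = np.ascontiguousarray(mesh.triangles, dtype=np.float64)
    nx, ny, nz = out.shape
    jx, jy = 0.31234e-3, 0.52718e-3
    xmin = tris[:, :, 0].min(axis=1)
    xmax = tris[:, :, 0].max(axis=1)
    ymin = tris[:, :, 1].min(axis=1)
    ymax = tris[:, :, 1].max(axis=1)
    ix0 = np.clip(np.ceil((xmin - lo[0] - jx) / h).astype(np.int64), 0, nx - 1)
    ix1 = np.clip(np.floor((xmax - lo[0] - jx) / h).astype(np.int64), 0, nx - 1)
    iy0 = np.clip(np.ceil((ymin - lo[1] - jy) / h).astype(np.int64), 0, ny - 1)
    iy1 = np.clip(np.floor((ymax - lo[1] - jy) / h).astype(np.int64), 0, ny - 1)
    valid = (ix0 <= ix1) & (iy0 <= iy1)
    ix0, ix1, iy0, iy1 = ix0[valid], ix1[valid], iy0[valid], iy1[valid]
    tris = tris[valid]
    if len(tris) == 0:
        return
    starts = np.cumsum(_bin_count(ix0, ix1, iy0, iy1, nx, ny))
    items = _bin_fill(ix0, ix1, iy0, iy1, ny, starts)
    _fill_parity(tris, starts, items, nx, ny, nz, lo[0], lo[1], lo[2], h, label, out)


LABELS = {1: "bone", 2: "cave", 3: "skin"}


def rasterize_scene(
    scene: Scene, voxel_size: float, bounds: np.ndarray | None = None, margin: float = 2.0
) -> imaging.LabelVolume:
    """Voxelize a scene into an integer label volume (0 bg, 1 bone, 2 cave, 3 skin).

    Closed meshes are filled by column-crossing parity; the open skin sheet is
    rasterized as a one-voxel-thick shell.  Labels are mutually exclusive with
    precedence bone > cave > skin.
    """
    if voxel_size > imaging.MAX_VOXEL_MM + 1e-12:
        raise ValueError(
            f"voxel_size {voxel_size} mm violates the <=1 mm slice-thickness criterion"
        )
    meshes = [m for m in (scene.bone_mesh, scene.cave_mesh, scene.skin_mesh)
              if m is not None and len(m.faces)]
    if bounds is None:
        if not meshes:
            affine = np.diag([voxel_size] * 3 + [1.0])
            return imaging.LabelVolume(
                data=np.zeros((2, 2, 2), dtype=np.int16), affine=affine, label_names=LABELS
            )
        all_lo = np.min([m.bounds[0] for m in meshes], axis=0) - margin
        all_hi = np.max([m.bounds[1] for m in meshes], axis=0) + margin
    else:
        all_lo, all_hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    h = float(voxel_size)
    shape = np.ceil((all_hi - all_lo) / h).astype(int) + 1
    # cell-centered grid: voxel centers are staggered half a voxel off the
    # bounds, which avoids degenerate alignments of lattice and geometry
    origin = all_lo + h / 2.0
    out = np.zeros(tuple(shape), dtype=np.int16)
    if scene.bone_mesh is not None and len(scene.bone_mesh.faces):
        _fill_mesh(scene.bone_mesh, out, origin, h, 1)
    if scene.cave_mesh is not None and len(scene.cave_mesh.faces):
        _fill_mesh(scene.cave_mesh, out, origin, h, 2)
    if scene.skin_mesh is not None and len(scene.skin_mesh.faces):
        v, f = trimesh.remesh.subdivide_to_size(
            scene.skin_mesh.vertices, scene.skin_mesh.faces, max_edge=h * 0.7
        )
        idx = np.round((v - origin) / h).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[ok]
        vals = out[idx[:, 0], idx[:, 1], idx[:, 2]]
        free = vals == 0
        out[idx[free, 0], idx[free, 1], idx[free, 2]] = 3
    affine = np.diag([h, h, h, 1.0])
    affine[:3, 3] = origin
    return imaging.LabelVolume(data=out, affine=affine, label_names=dict(LABELS))


def rasterize_ground_truth(
    config: PhantomConfig, voxel_size: float, bounds: np.ndarray
) -> imaging.LabelVolume:
    """Label volume evaluated from the phantom's implicit solids.

    Independent of every mesh/ray code path: voxel centers are classified by
    the analytic signed-distance fields, so this is the reference labelling
    used by the voxel ray-marching oracle.
    """
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    h = float(voxel_size)
    if not config.canonical_frame:
        raise ValueError("implicit labelling requires the canonical frame")
    shape = np.ceil((hi - lo) / h).astype(int) + 1
    origin = lo + h / 2.0  # cell-centered, as in rasterize_scene
    out = _label_grid(
        origin, h, shape, *_kernel_args(config),
        config.cave_center.astype(np.float64),
        np.asarray(config.cave_radii, dtype=np.float64),
    )
    affine = np.diag([h, h, h, 1.0])
    affine[:3, 3] = origin
    return imaging.LabelVolume(data=out, affine=affine, label_names=dict(LABELS))


# ---------------------------------------------------------------------------
# scene persistence


def save_scene(scene: Scene, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    imaging.write_mesh(scene.bone_mesh, d / "bone.ply")
    imaging.write_mesh(scene.cave_mesh, d / "cave.ply")
    imaging.write_mesh(scene.skin_mesh, d / "skin.ply")
    imaging.write_landmarks_json(scene.landmarks, d / "landmarks.json")
    imaging.write_landmarks_fcsv(scene.landmarks, d / "landmarks.fcsv")
    meta = {"side": scene.side}
    (d / "meta.json").write_text(json.dumps(meta))
    if scene.ground_truth is not None:
        scene.ground_truth.save(d / "config.yaml")


def load_scene(directory) -> Scene:
    d = Path(directory)
    landmarks = imaging.read_landmarks_json(d / "landmarks.json")
    meta = json.loads((d / "meta.json").read_text())
    gt = PhantomConfig.load(d / "config.yaml") if (d / "config.yaml").exists() else None
    occ = np.array([v for k, v in sorted(landmarks.items()) if k.startswith("occlusal")])
    fid = np.array([v for k, v in sorted(landmarks.items()) if k.startswith("fiducial")])
    plane = make_horizontal_plane(
        landmarks["mouth_angle"], occ, cranial_reference=fid.mean(axis=0)
    )
    return Scene(
        bone_mesh=imaging.read_mesh(d / "bone.ply"),
        cave_mesh=imaging.read_mesh(d / "cave.ply"),
        skin_mesh=imaging.read_mesh(d / "skin.ply"),
        landmarks=landmarks,
        horizontal_plane=plane,
        side=meta["side"],
        ground_truth=gt,
    )
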