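"""Paired-landmark rigid registration (Kabsch / orthogonal Procrustes).

Mirrors the clinical workflow of aligning a CT and an MRI frame on a handful
of fiducial points placed on structures visible in both (here: semicircular
canal stand-ins).  No scaling is estimated: both frames are metric (mm).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: FRE above which alignment is not considered "satisfactory" (mm).  Matches
#: the 1 mm slice-thickness inclusion criterion used for the source imaging.
DEFAULT_FRE_WARN_MM = 1.0


class DegenerateConfigurationError(ValueError):
    """Raised when landmark geometry cannot determine a unique rigid motion."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R @ x + t (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation has det != +1 (reflection not allowed)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True).as_matrix()
        return cls(R, np.asarray(translation, float))

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def save(self, path) -> None:
        """Write as a plain-text 4x4 homogeneous matrix."""
        np.savetxt(path, self.matrix, fmt="%.12g")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        M = np.loadtxt(path)
        if M.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix in {path}, got {M.shape}")
        return cls(M[:3, :3], M[:3, 3])


@dataclass
class RegistrationReport:
    transform: RigidTransform
    fre_rmse: float
    per_point_residuals: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "matrix": self.transform.matrix.tolist(),
            "fre_rmse_mm": float(self.fre_rmse),
            "per_point_residuals_mm": [float(r) for r in self.per_point_residuals],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def fit_rigid(
    source_points: np.ndarray,
    target_points: np.ndarray,
    fre_warn_mm: float = DEFAULT_FRE_WARN_MM,
) -> RegistrationReport:
    """Least-squares rigid alignment of paired points (SVD Kabsch).

    Finds the proper rigid motion minimizing sum ||R s_i + t - t_i||^2.
    Reflections are excluded by a determinant sign correction, so the result
    is always a physically realizable motion.

    Raises
    ------
    DegenerateConfigurationError
        Fewer than 3 pairs, mismatched counts, or (near-)collinear points.
    """
    S = np.asarray(source_points, dtype=float)
    T = np.asarray(target_points, dtype=float)
    if S.ndim != 2 or S.shape[1] != 3 or S.shape != T.shape:
        raise DegenerateConfigurationError(
            f"need equal-count Nx3 point sets, got {S.shape} and {T.shape}"
        )
    n = S.shape[0]
    if n < 3:
        raise DegenerateConfigurationError(f"need at least 3 point pairs, got {n}")
    s_mean = S.mean(axis=0)
    t_mean = T.mean(axis=0)
    Sc = S - s_mean
    Tc = T - t_mean
    # collinearity: second singular value of the centered cloud ~ 0
    sv = np.linalg.svd(Sc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateConfigurationError("source points are collinear")
    H = Sc.T @ Tc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = t_mean - R @ s_mean
    transform = RigidTransform(R, t)
    residuals = np.linalg.norm(transform.apply(S) - T, axis=1)
    fre = float(np.sqrt(np.mean(residuals**2)))
    if fre > fre_warn_mm:
        warnings.warn(
            f"fiducial registration error {fre:.2f} mm exceeds "
            f"{fre_warn_mm:.2f} mm; alignment may not be satisfactory",
            stacklevel=2,
        )
    return RegistrationReport(transform=transform, fre_rmse=fre, per_point_residuals=residuals)


def apply_rigid(transform: RigidTransform, obj):
    """Apply a rigid motion to points, a mesh, or a Scene (returns same kind)."""
    import trimesh

    from .phantom import Scene  # local import to avoid a cycle

    if isinstance(obj, Scene):
        return obj.transformed(transform)
    if isinstance(obj, trimesh.Trimesh):
        out = obj.copy()
        out.apply_transform(transform.matrix)
        return out
    return transform.apply(obj)
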