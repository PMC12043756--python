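"""The clinical measurement frame: the horizontal plane through the angle of
the mouth.

Entry-point heights in this package are signed distances (mm) from a plane
obtained by least-squares fitting the functional occlusal plane (bite plane)
and translating it to pass through the angle of the mouth; positive heights
are cranial ("above"), negative caudal ("below").  Lateral offsets are
in-plane Euclidean distances from the angle of the mouth, reported as
non-negative values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegeneratePlaneError(ValueError):
    """Occlusal points do not determine a plane (collinear or < 3)."""


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


@dataclass(frozen=True)
class HorizontalPlane:
    """Plane through ``origin`` (angle of mouth) with unit ``normal`` pointing cranially."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-9):
            raise ValueError("normal must be unit length")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "normal", n)

    def height(self, point: np.ndarray) -> float:
        """Signed height of a point: + above (cranial), - below (caudal)."""
        return float(np.dot(np.asarray(point, dtype=float) - self.origin, self.normal))

    def project(self, point: np.ndarray) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        return p - self.height(p) * self.normal

    def transformed(self, transform) -> "HorizontalPlane":
        return HorizontalPlane(
            transform.apply(self.origin), transform.rotation @ self.normal
        )


@dataclass(frozen=True)
class CheekCoordinate:
    """A skin point expressed in the clinical frame: (signed height, lateral offset)."""

    height: float
    lateral_offset: float
    point: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))
        if self.lateral_offset < 0:
            raise ValueError("lateral_offset must be >= 0")


def make_horizontal_plane(
    mouth_angle: np.ndarray,
    occlusal_points: np.ndarray,
    cranial_reference: np.ndarray | None = None,
) -> HorizontalPlane:
    """Least-squares occlusal plane translated through the angle of the mouth.

    Parameters
    ----------
    mouth_angle : (3,) point, the oral commissure.
    occlusal_points : (N>=3, 3) points on the functional occlusal plane.
    cranial_reference : optional point known to lie cranially of the plane
        (e.g. the centroid of the skull-base fiducials); fixes the sign of the
        normal so that heights are + above / - below.  Without it the normal's
        hemisphere is chosen toward +z.
    """
    pts = np.asarray(occlusal_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegeneratePlaneError("need at least 3 occlusal points")
    centered = pts - pts.mean(axis=0)
    # plane normal = least singular vector of the centered cloud
    _, sv, Vt = np.linalg.svd(centered, full_matrices=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegeneratePlaneError("occlusal points are collinear")
    normal = _unit(Vt[2])
    mouth = np.asarray(mouth_angle, dtype=float)
    if cranial_reference is not None:
        if np.dot(np.asarray(cranial_reference, float) - mouth, normal) < 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal
    return HorizontalPlane(origin=mouth, normal=normal)


def cheek_coordinate(
    plane: HorizontalPlane, point: np.ndarray, mouth_angle: np.ndarray | None = None
) -> CheekCoordinate:
    """Express a skin point as (signed height, in-plane lateral offset).

    The lateral offset is the Euclidean distance between the in-plane
    projections of the point and the mouth angle — a calliper-style distance,
    not an arc length along the skin.
    """
    mouth = plane.origin if mouth_angle is None else np.asarray(mouth_angle, float)
    p = np.asarray(point, dtype=float)
    h = plane.height(p)
    in_plane = (p - mouth) - np.dot(p - mouth, plane.normal) * plane.normal
    return CheekCoordinate(height=h, lateral_offset=float(np.linalg.norm(in_plane)), point=p)
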