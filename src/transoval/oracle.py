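"""Brute-force voxel ray-marching reference for trajectory visibility.

This is the independent cross-check for the mesh ray caster: rays are marched
in fixed small steps through an integer label volume, and a ray is accessible
when the first non-background label it meets is the cave, not bone.  For
phantom scenes the label volume can come straight from the analytic solids
(:func:`transoval.phantom.rasterize_ground_truth`), so no mesh or
triangle-intersection code is shared with the path being checked.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .imaging import LabelVolume

DEFAULT_STEP_MM = 0.25


@njit(cache=True)
def _march_kernel(data, origin, h, entry, dirs, step, t_starts, out):
    # Trilinearly interpolated occupancy per label, thresholded at 0.5: puts
    # the effective surface at the half-occupancy crossing instead of
    # dilating solids by half a voxel as nearest-voxel lookup would.
    nx, ny, nz = data.shape
    n = dirs.shape[0]
    for i in range(n):
        dx, dy, dz = dirs[i, 0], dirs[i, 1], dirs[i, 2]
        # ray / grid-box exit distance
        t_hi = 1e9
        for k in range(3):
            d = dirs[i, k]
            lo = origin[k]
            hi = origin[k] + h * (data.shape[k] - 1)
            if abs(d) > 1e-12:
                t1 = (lo - entry[k]) / d
                t2 = (hi - entry[k]) / d
                tmax = t1 if t1 > t2 else t2
                if tmax < t_hi:
                    t_hi = tmax
        t = t_starts[i]
        res = 0
        while t <= t_hi:
            fx = (entry[0] + t * dx - origin[0]) / h
            fy = (entry[1] + t * dy - origin[1]) / h
            fz = (entry[2] + t * dz - origin[2]) / h
            ix = int(np.floor(fx))
            iy = int(np.floor(fy))
            iz = int(np.floor(fz))
            if 0 <= ix < nx - 1 and 0 <= iy < ny - 1 and 0 <= iz < nz - 1:
                tx = fx - ix
                ty = fy - iy
                tz = fz - iz
                bone = 0.0
                cave = 0.0
                for a in range(2):
                    wa = tx if a == 1 else 1.0 - tx
                    for b in range(2):
                        wb = ty if b == 1 else 1.0 - ty
                        for c in range(2):
                            wc = tz if c == 1 else 1.0 - tz
                            w = wa * wb * wc
                            lab = data[ix + a, iy + b, iz + c]
                            if lab == 1:
                                bone += w
                            elif lab == 2:
                                cave += w
                if bone >= 0.5:
                    res = 0
                    break
                if cave >= 0.5:
                    res = 1
                    break
            t += step
        out[i] = res


def accessible_mask_voxel(
    volume: LabelVolume,
    entry: np.ndarray,
    sample_points: np.ndarray,
    step: float = DEFAULT_STEP_MM,
) -> np.ndarray:
    """Per-sample accessibility by voxel marching (1 = cave reached first).

    Marching starts just past the entry point and uses nearest-voxel label
    lookup; the volume's affine must be axis-aligned isotropic (as produced by
    the rasterizers in this package).
    """
    A = volume.affine
    off = A[:3, :3] - np.diag(np.diag(A[:3, :3]))
    if not np.allclose(off, 0.0) or not np.allclose(
        np.diag(A[:3, :3]), A[0, 0]
    ):
        raise ValueError("oracle requires an axis-aligned isotropic affine")
    h = float(A[0, 0])
    origin = A[:3, 3].copy()
    entry = np.asarray(entry, dtype=np.float64)
    samples = np.atleast_2d(np.asarray(sample_points, dtype=np.float64))
    dirs = samples - entry[None, :]
    norms = np.linalg.norm(dirs, axis=1)
    dirs = dirs / norms[:, None]
    t_starts = np.full(len(dirs), step)
    out = np.zeros(len(dirs), dtype=np.int8)
    _march_kernel(
        np.ascontiguousarray(volume.data.astype(np.int16)),
        origin,
        h,
        entry,
        np.ascontiguousarray(dirs),
        float(step),
        t_starts,
        out,
    )
    return out.astype(bool)


def accessible_fraction_voxel(
    volume: LabelVolume,
    entry: np.ndarray,
    sample_points: np.ndarray,
    step: float = DEFAULT_STEP_MM,
) -> float:
    mask = accessible_mask_voxel(volume, entry, sample_points, step=step)
    return float(mask.mean()) if len(mask) else 0.0


def corridor_bounds(config, entries: np.ndarray, margin: float = 4.0) -> np.ndarray:
    """Axis-aligned bounds covering the entry points, canal and cave."""
    entries = np.atleast_2d(entries)
    pts = [entries]
    pts.append(config.fo_center[None, :] + np.array([[-1.0], [1.0]]) * (
        config.fo_canal_length / 2.0 + max(config.fo_radii) + config.collar_wall_mm + 2.0
    ) * np.array([[1.0, 1.0, 1.0]]))
    pts.append(config.cave_center[None, :] - np.asarray(config.cave_radii)[None, :])
    pts.append(config.cave_center[None, :] + np.asarray(config.cave_radii)[None, :])
    allp = np.vstack(pts)
    return np.array([allp.min(axis=0) - margin, allp.max(axis=0) + margin])
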