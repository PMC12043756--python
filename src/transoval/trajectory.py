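"""Trajectory analysis: which cheek entry points reach Meckel's cave through
the foramen ovale.

An entry point is assessed by casting straight rays from it through a dense,
stratified sample of the foraminal aperture (the extracranial rim of the bony
canal).  A sample is *accessible* when its ray reaches the cave before hitting
any bone — i.e. it traverses the canal and is not occluded by the canal wall,
the foraminal rims, the mandibular ramus or the skull-base plate.  The entry
is then classified:

* ``easy``      accessible fraction >= 0.5 through a distinct (non-slit-like)
                aperture;
* ``possible``  some but not enough of the aperture reaches the cave, or the
                aperture projects as a narrow slit;
* ``blocked``   no ray reaches the cave.

Scanning entries along a cranio-caudal line on the cheek (just in front of the
anterior edge of the mandibular ramus) yields the extreme span (outermost
heights with any access) and the easy span; Härtel's classical trigeminal axis
(impression midpoint -> FO centre -> cheek) gives the Einstichpunkt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .frames import CheekCoordinate, cheek_coordinate
from .phantom import Scene
from .raycast import TriangleSet, count_hits, first_hit, points_in_mesh

DEFAULT_N_RAYS = 1000
DEFAULT_SLIT_THRESHOLD_MM = 2.0
DEFAULT_RIM_INSET_MM = 0.3
DEFAULT_HEIGHTS = np.arange(-45.0, 30.0 + 0.5, 1.0)
REFINE_TOL_MM = 0.1


class NoPatentForamenError(RuntimeError):
    pass


class EntryPointError(ValueError):
    pass


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# aperture


@dataclass
class ApertureModel:
    """The extracranial rim of the foraminal canal and a sampling of its interior.

    ``rim_points`` is a closed, ordered loop on the plane normal to the canal
    axis, inset slightly intracranially from the canal end so the slice cuts
    the canal wall rather than the flat rim face.  The medial/lateral split is
    the half-plane through the centroid normal to the medial-lateral axis of
    the rim's best-fit ellipse.
    """

    rim_points: np.ndarray
    centroid: np.ndarray
    normal: np.ndarray  # canal axis, pointing intracranially
    area: float
    ellipse_axes: tuple[float, float]  # (medial-lateral, antero-posterior) semi-axes
    ellipse_dirs: np.ndarray  # (2, 3) unit vectors in the rim plane
    medial_dir: np.ndarray  # unit vector in rim plane pointing medially
    canal_length: float
    side: str
    _sample_cache: dict = field(default_factory=dict, repr=False)

    @property
    def radius(self) -> float:
        """Circumradius of the rim about the centroid (for cone prefilters)."""
        return float(np.max(np.linalg.norm(self.rim_points - self.centroid, axis=1)))

    def sample_points(self, n: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Stratified jittered samples of the rim interior; (points, medial_mask).

        A jittered grid in the rim plane is restricted to the rim polygon, so
        the sample density is uniform and the Monte-Carlo error of aperture
        fractions decays faster than for i.i.d. sampling.
        """
        key = (n, seed)
        if key not in self._sample_cache:
            e1, e2 = self.ellipse_dirs
            rel = self.rim_points - self.centroid
            u = rel @ e1
            v = rel @ e2
            u0, u1, v0, v1 = u.min(), u.max(), v.min(), v.max()
            bbox_area = (u1 - u0) * (v1 - v0)
            cell = np.sqrt(bbox_area / max(n * bbox_area / max(self.area, 1e-9), 1))
            nu = max(int(np.ceil((u1 - u0) / cell)), 1)
            nv = max(int(np.ceil((v1 - v0) / cell)), 1)
            rng = np.random.default_rng(seed)
            gu = u0 + (np.arange(nu)[:, None] + rng.random((nu, nv))) * (u1 - u0) / nu
            gv = v0 + (np.arange(nv)[None, :] + rng.random((nu, nv))) * (v1 - v0) / nv
            pu = gu.ravel()
            pv = gv.ravel()
            inside = _points_in_polygon(np.column_stack([pu, pv]), np.column_stack([u, v]))
            pu, pv = pu[inside], pv[inside]
            pts = self.centroid + pu[:, None] * e1 + pv[:, None] * e2
            medial = (pts - self.centroid) @ self.medial_dir > 0
            self._sample_cache[key] = (pts, medial)
        return self._sample_cache[key]


def _points_in_polygon(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd point-in-polygon test in 2D."""
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    j = n - 1
    for i in range(n):
        xi, yi = poly[i]
        xj, yj = poly[j]
        crosses = ((yi > y) != (yj > y)) & (
            x < (xj - xi) * (y - yi) / (yj - yi + 1e-300) + xi
        )
        inside ^= crosses
        j = i
    return inside


def _fit_ellipse(uv: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Direct least-squares ellipse fit (Fitzgibbon) of 2D boundary points.

    Returns (center, semi-axes, row-unit-vector axis directions).  Exact when
    the points lie on a true ellipse; falls back to arc-length-weighted
    second moments if the constrained eigenproblem degenerates.
    """
    x, y = uv[:, 0], uv[:, 1]
    try:
        D = np.column_stack([x**2, x * y, y**2, x, y, np.ones_like(x)])
        S = D.T @ D
        C = np.zeros((6, 6))
        C[0, 2] = C[2, 0] = 2.0
        C[1, 1] = -1.0
        evals, evecs = np.linalg.eig(np.linalg.solve(S, C))
        mask = np.isreal(evals) & (np.real(evals) > 1e-12)
        if not mask.any():
            raise np.linalg.LinAlgError("no elliptical solution")
        a_vec = np.real(evecs[:, np.argmax(np.real(evals) * mask)])
        A, B, Cq, Dq, E, F = a_vec
        den = B**2 - 4 * A * Cq
        x0 = (2 * Cq * Dq - B * E) / den
        y0 = (2 * A * E - B * Dq) / den
        Fc = A * x0**2 + B * x0 * y0 + Cq * y0**2 + Dq * x0 + E * y0 + F
        M = np.array([[A, B / 2.0], [B / 2.0, Cq]])
        lam, vec = np.linalg.eigh(M)
        semi = np.sqrt(-Fc / lam)
        if not np.all(np.isfinite(semi)):
            raise np.linalg.LinAlgError("degenerate conic")
        return np.array([x0, y0]), semi, vec.T
    except np.linalg.LinAlgError:
        seg_vec = np.roll(uv, -1, axis=0) - uv
        w = np.linalg.norm(seg_vec, axis=1)
        mid = uv + 0.5 * seg_vec
        mu = np.average(mid, axis=0, weights=w)
        d = mid - mu
        cov = (d * w[:, None]).T @ d / w.sum()
        evals2, evecs2 = np.linalg.eigh(cov)
        return mu, np.sqrt(2.0 * np.maximum(evals2, 0.0)), evecs2.T


def build_aperture(
    scene: Scene,
    inset: float = DEFAULT_RIM_INSET_MM,
    canal: tuple[np.ndarray, np.ndarray, float] | None = None,
) -> ApertureModel:
    """Extract the extracranial canal rim from the bone mesh.

    ``canal`` may supply (fo_center, fo_axis, canal_length) explicitly; by
    default it is taken from the scene's ground truth.  Raises
    :class:`NoPatentForamenError` when the axis segment through the canal hits
    bone (sealed or absent foramen).
    """
    if canal is not None:
        center, axis, length = canal
        center = np.asarray(center, float)
        axis = _unit(axis)
    elif scene.ground_truth is not None:
        gt = scene.ground_truth
        center, axis, length = gt.fo_center, gt.fo_axis, gt.fo_canal_length
    else:
        raise ValueError("scene has no ground truth; pass canal=(center, axis, length)")

    bone_tris = np.asarray(scene.bone_mesh.triangles, dtype=np.float64)
    # patency: the straight segment along the axis through the canal must be bone-free
    seg_len = length + 10.0
    origin = center - 0.5 * seg_len * axis
    n_cross = count_hits(origin[None, :], axis[None, :], bone_tris, t_max=[seg_len])[0]
    if n_cross > 0:
        raise NoPatentForamenError(
            "no patent foramen: canal axis segment intersects bone "
            f"({n_cross} crossings)"
        )

    plane_origin = center - (0.5 * length - inset) * axis
    segments = trimesh.intersections.mesh_plane(
        scene.bone_mesh, plane_normal=axis, plane_origin=plane_origin
    )
    if len(segments) == 0:
        raise NoPatentForamenError("no patent foramen: rim plane does not cut bone")
    e1 = _unit(np.array([1.0, 0.0, 0.0]) - axis[0] * axis)
    e2 = np.cross(axis, e1)

    path = trimesh.load_path(segments)
    loops = [np.asarray(d) for d in path.discrete]
    best = None
    for loop in loops:
        if len(loop) < 3 or np.linalg.norm(loop[0] - loop[-1]) > 1e-6:
            continue
        pts = loop[:-1]
        u = (pts - plane_origin) @ e1
        v = (pts - plane_origin) @ e2
        if not _points_in_polygon(np.zeros((1, 2)), np.column_stack([u, v]))[0]:
            continue
        area = abs(float(np.sum(u * np.roll(v, -1) - np.roll(u, -1) * v)) / 2.0)
        if best is None or area < best[1]:
            best = (pts, area, u, v)
    if best is None:
        raise NoPatentForamenError("no patent foramen: no closed rim loop encircles the axis")
    rim, area, u, v = best

    uv = np.column_stack([u, v])
    mu, semi_axes, evecs = _fit_ellipse(uv)
    dirs3 = (evecs[:, :, None] * np.stack([e1, e2])[None, :, :]).sum(axis=1)
    # medial-lateral = the ellipse axis most aligned with world x
    ml_idx = int(np.argmax(np.abs(dirs3 @ np.array([1.0, 0.0, 0.0]))))
    ap_idx = 1 - ml_idx
    ml_dir = dirs3[ml_idx]
    ap_dir = dirs3[ap_idx]
    centroid = plane_origin + mu[0] * e1 + mu[1] * e2
    medial_sign = -1.0 if scene.side == "right" else 1.0
    medial_dir = ml_dir if ml_dir[0] * medial_sign > 0 else -ml_dir
    if ap_dir[1] < 0:  # orient the AP axis anteriorly
        ap_dir = -ap_dir
    # basis (medial, anterior): anatomical, so mirrored sides sample mirrored points
    return ApertureModel(
        rim_points=rim,
        centroid=centroid,
        normal=axis,
        area=area,
        ellipse_axes=(float(semi_axes[ml_idx]), float(semi_axes[ap_idx])),
        ellipse_dirs=np.stack([_unit(medial_dir), _unit(ap_dir)]),
        medial_dir=_unit(medial_dir),
        canal_length=float(length),
        side=scene.side,
    )


# ---------------------------------------------------------------------------
# entry-point assessment


@dataclass
class TrajectoryAssessment:
    entry: CheekCoordinate
    accessible_fraction: float
    medial_fraction: float
    classification: str  # blocked | possible | easy
    aperture_projection: dict
    n_rays: int
    reason: str | None = None


class TrajectoryContext:
    """Cached geometry for repeated assessments on one scene/aperture pair."""

    def __init__(self, scene: Scene, aperture: ApertureModel):
        self.scene = scene
        self.aperture = aperture
        self.bone = TriangleSet.from_mesh(scene.bone_mesh)
        self.cave_tris = np.ascontiguousarray(scene.cave_mesh.triangles, dtype=np.float64)
        self.skin_tris = np.ascontiguousarray(scene.skin_mesh.triangles, dtype=np.float64)
        self._skin_tree = cKDTree(scene.skin_mesh.vertices)
        # least-squares skin plane (the sheet is planar by construction)
        verts = scene.skin_mesh.vertices
        c = verts.mean(axis=0)
        _, _, Vt = np.linalg.svd(verts - c, full_matrices=False)
        n = Vt[2]
        self.skin_plane_point = c
        self.skin_plane_normal = _unit(n)
        cave_c = scene.cave_mesh.vertices.mean(axis=0)
        self.cave_reach = float(
            np.max(np.linalg.norm(scene.cave_mesh.vertices - cave_c, axis=1))
        )
        self.cave_center = cave_c

    def snap_to_skin(self, point: np.ndarray) -> np.ndarray:
        """Exact closest point on the skin sheet near ``point``."""
        point = np.asarray(point, dtype=float)
        _, idx = self._skin_tree.query(point, k=8)
        mesh = self.scene.skin_mesh
        faces = np.unique(mesh.vertex_faces[np.atleast_1d(idx)])
        faces = faces[faces >= 0]
        tris = mesh.triangles[faces]
        pts = trimesh.triangles.closest_point(
            tris, np.repeat(point[None, :], len(tris), axis=0)
        )
        d = np.linalg.norm(pts - point, axis=1)
        return pts[int(np.argmin(d))]


def assess_entry_point(
    scene: Scene,
    aperture: ApertureModel,
    entry_point: np.ndarray,
    n_rays: int = DEFAULT_N_RAYS,
    slit_threshold: float = DEFAULT_SLIT_THRESHOLD_MM,
    sample_seed: int = 0,
    snap: bool = True,
    context: TrajectoryContext | None = None,
) -> TrajectoryAssessment:
    """Classify one cheek entry point by ray visibility of the cave.

    Rays run from the entry to stratified samples of the aperture; a sample is
    accessible iff its ray's first intersection is the cave, not bone.  The
    aperture's outline as seen from the entry (orthographic projection along
    the entry->centroid direction) yields the slit-likeness flag.
    """
    if n_rays < 100:
        raise ValueError("n_rays must be >= 100 for a stable aperture fraction")
    if context is None:
        context = TrajectoryContext(scene, aperture)
    entry = np.asarray(entry_point, dtype=float)
    if snap:
        entry = context.snap_to_skin(entry)
    if points_in_mesh(entry[None, :], context.bone.tris)[0]:
        raise EntryPointError("entry point lies inside bone")

    samples, medial_mask = aperture.sample_points(n_rays, seed=sample_seed)
    dirs = samples - entry[None, :]
    d_ap = float(np.linalg.norm(aperture.centroid - entry))
    t_max = (np.linalg.norm(context.cave_center - entry) + context.cave_reach + 5.0)
    bone_sub = context.bone.cone_subset(
        entry, aperture.centroid, aperture.radius, t_max=t_max, margin=1.0
    )
    origins = np.repeat(entry[None, :], len(samples), axis=0)
    t_bone = first_hit(origins, dirs, bone_sub)
    t_cave = first_hit(origins, dirs, context.cave_tris)
    accessible = t_cave < t_bone
    fraction = float(np.mean(accessible)) if len(accessible) else 0.0
    medial_fraction = (
        float(np.mean(accessible[medial_mask])) if medial_mask.any() else 0.0
    )

    proj = _aperture_projection(aperture, entry, slit_threshold)

    reason = None
    if fraction == 0.0:
        classification = "blocked"
        gt = scene.ground_truth
        if gt is not None and gt.canonical_frame and gt.ramus_box() is not None:
            sign = gt.lateral_sign
            if sign * entry[0] > sign * gt.ramus_anterior_x:
                finite = np.isfinite(t_bone)
                hits = origins[finite] + t_bone[finite, None] * dirs[finite]
                box = gt.ramus_box()
                if len(hits) and np.any(
                    np.all(np.abs(hits - box[0]) <= box[1] + 1e-6, axis=1)
                ):
                    reason = "mandible occlusion"
    elif fraction >= 0.5 and not proj["slitlike"]:
        classification = "easy"
    else:
        classification = "possible"

    coord = cheek_coordinate(scene.horizontal_plane, entry)
    return TrajectoryAssessment(
        entry=coord,
        accessible_fraction=fraction,
        medial_fraction=medial_fraction,
        classification=classification,
        aperture_projection=proj,
        n_rays=len(samples),
        reason=reason,
    )


def _aperture_projection(aperture: ApertureModel, entry: np.ndarray, slit_threshold: float) -> dict:
    """Orthographic outline of the rim as seen from the entry point."""
    d = _unit(aperture.centroid - entry)
    p1 = np.array([0.0, 0.0, 1.0]) - d[2] * d
    if np.linalg.norm(p1) < 1e-6:
        p1 = np.array([1.0, 0.0, 0.0]) - d[0] * d
    p1 = _unit(p1)
    p2 = np.cross(d, p1)
    rel = aperture.rim_points - aperture.centroid
    uv = np.column_stack([rel @ p1, rel @ p2])
    u, v = uv[:, 0], uv[:, 1]
    area = abs(float(np.sum(u * np.roll(v, -1) - np.roll(u, -1) * v)) / 2.0)
    min_w, max_w = _caliper_widths(uv)
    aspect = float(max_w / min_w) if min_w > 1e-9 else float("inf")
    return {
        "area": area,
        "aspect_ratio": aspect,
        "min_width": float(min_w),
        "max_width": float(max_w),
        "slitlike": bool(min_w < slit_threshold),
    }


def _caliper_widths(pts: np.ndarray) -> tuple[float, float]:
    """(min, max) caliper widths of a 2D point set (rotating-calipers style)."""
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError:
        # degenerate: nearly collinear projection
        c = pts.mean(axis=0)
        d = pts - c
        _, _, Vt = np.linalg.svd(d, full_matrices=False)
        major = d @ Vt[0]
        minor = d @ Vt[1]
        return float(minor.max() - minor.min()), float(major.max() - major.min())
    min_w = np.inf
    n = len(hp)
    for i in range(n):
        e = hp[(i + 1) % n] - hp[i]
        ln = np.linalg.norm(e)
        if ln < 1e-12:
            continue
        nrm = np.array([-e[1], e[0]]) / ln
        proj = (hp - hp[i]) @ nrm
        min_w = min(min_w, proj.max() - proj.min())
    diffs = hp[:, None, :] - hp[None, :, :]
    max_w = float(np.sqrt((diffs**2).sum(axis=2).max()))
    return float(min_w), max_w


# ---------------------------------------------------------------------------
# entry-line scanning


@dataclass
class SpanResult:
    """Signed-height bounds of the accessible and easy entry spans for one side."""

    lower_extreme: float | None
    upper_extreme: float | None
    lower_easy: float | None
    upper_easy: float | None
    side: str
    easy_intervals: list[tuple[float, float]] = field(default_factory=list)
    table: pd.DataFrame | None = field(default=None, repr=False)
    warning: str | None = None

    @property
    def extreme_width(self) -> float | None:
        if self.lower_extreme is None or self.upper_extreme is None:
            return None
        return self.upper_extreme - self.lower_extreme

    @property
    def easy_width(self) -> float | None:
        if self.lower_easy is None or self.upper_easy is None:
            return None
        return self.upper_easy - self.lower_easy


def entry_line_point(
    scene: Scene,
    height: float,
    context: TrajectoryContext,
    anchor: np.ndarray | None = None,
) -> np.ndarray:
    """Point on the cheek entry line at a given signed height.

    The entry line runs through the anchor (default: the ``entry_anchor``
    landmark, 1 mm in front of the anterior edge of the mandibular ramus)
    along the steepest in-skin-plane direction of the height coordinate, so it
    is intrinsic to the anatomy and invariant under joint rigid motions.
    """
    if anchor is None:
        if "entry_anchor" not in scene.landmarks:
            raise EntryPointError("scene has no entry_anchor landmark; pass anchor=")
        anchor = scene.landmarks["entry_anchor"]
    anchor = context.snap_to_skin(np.asarray(anchor, dtype=float))
    n_h = scene.horizontal_plane.normal
    n_s = context.skin_plane_normal
    w = n_h - np.dot(n_h, n_s) * n_s
    wn = np.linalg.norm(w)
    if wn < 1e-9:
        raise EntryPointError("skin sheet is parallel to the horizontal plane")
    w = w / wn
    h_anchor = scene.horizontal_plane.height(anchor)
    step = (height - h_anchor) / np.dot(w, n_h)
    return context.snap_to_skin(anchor + step * w)


def scan_entry_line(
    scene: Scene,
    aperture: ApertureModel,
    lateral_anchor: np.ndarray | None = None,
    heights: np.ndarray = DEFAULT_HEIGHTS,
    n_rays: int = DEFAULT_N_RAYS,
    slit_threshold: float = DEFAULT_SLIT_THRESHOLD_MM,
    refine_tol: float = REFINE_TOL_MM,
    refine_n_rays: int | None = None,
    context: TrajectoryContext | None = None,
) -> SpanResult:
    """Scan the cheek entry line and locate extreme and easy span boundaries.

    A coarse scan on ``heights`` (default 1 mm grid, -45..+30 mm) is followed
    by bisection of each boundary to ``refine_tol`` (default 0.1 mm).  The
    bisection predicate is evaluated with ``refine_n_rays`` samples (default
    max(n_rays, 3000)): boundary location demands a tighter aperture-fraction
    estimate than the coarse scan, and a fixed refinement count keeps the
    refined boundaries stable when the scan ray count changes.  If several
    disjoint easy intervals exist, all are reported and the widest is
    designated primary.
    """
    if context is None:
        context = TrajectoryContext(scene, aperture)
    if refine_n_rays is None:
        refine_n_rays = max(n_rays, 3000)

    def assess_at(h: float, n: int = n_rays) -> TrajectoryAssessment:
        p = entry_line_point(scene, h, context, anchor=lateral_anchor)
        return assess_entry_point(
            scene, aperture, p, n_rays=n, slit_threshold=slit_threshold,
            snap=False, context=context,
        )

    heights = np.asarray(heights, dtype=float)
    rows = []
    results = {}
    for h in heights:
        a = assess_at(h)
        results[h] = a
        rows.append(
            {
                "height_mm": h,
                "achieved_height_mm": a.entry.height,
                "lateral_mm": a.entry.lateral_offset,
                "fraction": a.accessible_fraction,
                "medial_fraction": a.medial_fraction,
                "class": a.classification,
                "slitlike": a.aperture_projection["slitlike"],
            }
        )
    table = pd.DataFrame(rows)

    def bisect(h_in: float, h_out: float, pred) -> float:
        """Refine a boundary between an inside (pred True) and outside height.

        The high-count predicate may disagree with the coarse scan right at
        the bracket ends, so the bracket is first walked until it straddles
        the refined crossing.
        """
        cache: dict[float, bool] = {}

        def P(h: float) -> bool:
            if h not in cache:
                cache[h] = bool(pred(assess_at(h, refine_n_rays)))
            return cache[h]

        step = h_out - h_in
        tries = 0
        while not P(h_in) and tries < 6:
            h_in, h_out = h_in - step, h_in
            tries += 1
        if not P(h_in):
            return float(h_out)
        tries = 0
        while P(h_out) and tries < 6:
            h_in, h_out = h_out, h_out + step
            tries += 1
        if P(h_out):
            return float(h_out)
        while abs(h_out - h_in) > refine_tol:
            mid = 0.5 * (h_in + h_out)
            if P(mid):
                h_in = mid
            else:
                h_out = mid
        return 0.5 * (h_in + h_out)

    acc = table["fraction"].to_numpy() > 0
    easy = table["class"].to_numpy() == "easy"
    hs = table["height_mm"].to_numpy()

    def runs(mask):
        out = []
        i = 0
        while i < len(mask):
            if mask[i]:
                j = i
                while j + 1 < len(mask) and mask[j + 1]:
                    j += 1
                out.append((i, j))
                i = j + 1
            else:
                i += 1
        return out

    pred_acc = lambda a: a.accessible_fraction > 0
    pred_easy = lambda a: a.classification == "easy"

    lower_extreme = upper_extreme = None
    warning = None
    if acc.any():
        i0 = int(np.argmax(acc))
        i1 = len(acc) - 1 - int(np.argmax(acc[::-1]))
        lower_extreme = (
            bisect(hs[i0], hs[i0 - 1], pred_acc) if i0 > 0 else float(hs[i0])
        )
        upper_extreme = (
            bisect(hs[i1], hs[i1 + 1], pred_acc) if i1 < len(hs) - 1 else float(hs[i1])
        )
    else:
        warning = "no accessible entry anywhere on the scanned line"

    easy_intervals: list[tuple[float, float]] = []
    for i0, i1 in runs(easy):
        lo = bisect(hs[i0], hs[i0 - 1], pred_easy) if i0 > 0 else float(hs[i0])
        hi = bisect(hs[i1], hs[i1 + 1], pred_easy) if i1 < len(hs) - 1 else float(hs[i1])
        easy_intervals.append((lo, hi))
    lower_easy = upper_easy = None
    if easy_intervals:
        widths = [b - a for a, b in easy_intervals]
        lower_easy, upper_easy = easy_intervals[int(np.argmax(widths))]
        # numerical guard: easy span must sit inside the extreme span
        if lower_extreme is not None:
            lower_easy = max(lower_easy, lower_extreme)
            upper_easy = min(upper_easy, upper_extreme)

    return SpanResult(
        lower_extreme=lower_extreme,
        upper_extreme=upper_extreme,
        lower_easy=lower_easy,
        upper_easy=upper_easy,
        side=scene.side,
        easy_intervals=easy_intervals,
        table=table,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# Härtel's trigeminal axis


@dataclass
class HartelAxisResult:
    axis_origin: np.ndarray
    axis_through: np.ndarray
    einstichpunkt: np.ndarray
    einstich_height: float


def hartel_axis(
    scene: Scene,
    aperture: ApertureModel,
    context: TrajectoryContext | None = None,
    origin_offset: np.ndarray | None = None,
) -> HartelAxisResult:
    """Simulate Härtel's trigeminal axis and its skin exit (Einstichpunkt).

    The straight line from the trigeminal-impression midpoint through the FO
    centroid is extended extracranially until it pierces the cheek sheet.
    ``origin_offset`` shifts the axis origin (e.g. a 1-2 mm elevation along
    the horizontal-plane normal) before tracing.
    """
    if "impression_point" not in scene.landmarks:
        raise ValueError("scene lacks the impression_point landmark")
    if context is None:
        context = TrajectoryContext(scene, aperture)
    origin = np.asarray(scene.landmarks["impression_point"], dtype=float)
    if origin_offset is not None:
        origin = origin + np.asarray(origin_offset, dtype=float)
    direction = aperture.centroid - origin
    t = first_hit(origin[None, :], direction[None, :], context.skin_tris)[0]
    if not np.isfinite(t):
        raise RuntimeError("Härtel axis misses the skin sheet (sheet too small)")
    punkt = origin + t * direction
    return HartelAxisResult(
        axis_origin=origin,
        axis_through=aperture.centroid,
        einstichpunkt=punkt,
        einstich_height=scene.horizontal_plane.height(punkt),
    )


# ---------------------------------------------------------------------------
# recommendation


@dataclass
class EntryRecommendation:
    height: float
    downgraded: bool  # True when no easy span exists (best possible hit instead)


def recommend_entry(
    span: SpanResult,
    soft_tissue_offset: float = 0.0,
    target_height: float = -2.0,
) -> EntryRecommendation:
    """Recommended entry height on the cheek.

    The target (-2 mm by default, the optimal level) is clamped into the easy
    span, then lowered by ``soft_tissue_offset`` to pre-compensate the upward
    shift of the cheek soft tissues during needle insertion.  Without an easy
    span the best possible-hit height is returned with a downgrade flag.
    """
    if span.lower_easy is not None and span.upper_easy is not None:
        h = float(np.clip(target_height, span.lower_easy, span.upper_easy))
        return EntryRecommendation(height=h - soft_tissue_offset, downgraded=False)
    if span.table is None or not (span.table["fraction"] > 0).any():
        raise ValueError("no accessible entry at all; nothing to recommend")
    best = span.table.loc[span.table["fraction"].idxmax()]
    return EntryRecommendation(
        height=float(best["height_mm"]) - soft_tissue_offset, downgraded=True
    )
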