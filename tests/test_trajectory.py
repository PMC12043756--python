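import numpy as np
import pandas as pd
import pytest
import trimesh

import closedform
from transoval import phantom, trajectory
from transoval.frames import HorizontalPlane
from transoval.phantom import canonical_config, generate_phantom
from transoval.registration import RigidTransform
from transoval.trajectory import (
    ApertureModel,
    EntryPointError,
    NoPatentForamenError,
    SpanResult,
    TrajectoryContext,
    assess_entry_point,
    build_aperture,
    entry_line_point,
    hartel_axis,
    recommend_entry,
    scan_entry_line,
)


class TestBuildAperture:
    def test_circular_canal_area_matches_analytic(self, closedform_aperture):
        assert closedform_aperture.area == pytest.approx(
            np.pi * closedform.R_CANAL**2, rel=0.05
        )

    def test_elliptical_canal_axes_recovered(self):
        scene = generate_phantom(canonical_config(fo_radii=(4.0, 1.5), mesh_voxel_mm=0.35))
        ap = build_aperture(scene)
        assert ap.ellipse_axes[0] == pytest.approx(4.0, rel=0.1)
        assert ap.ellipse_axes[1] == pytest.approx(1.5, rel=0.1)

    def test_sealed_canal_raises_no_patent_foramen(self, coarse_scene):
        gt = coarse_scene.ground_truth
        plug = trimesh.creation.box(
            extents=[12.0, 12.0, 4.0],
            transform=trimesh.transformations.translation_matrix(gt.extracranial_exit),
        )
        sealed = phantom.Scene(
            bone_mesh=trimesh.util.concatenate([coarse_scene.bone_mesh, plug]),
            cave_mesh=coarse_scene.cave_mesh,
            skin_mesh=coarse_scene.skin_mesh,
            landmarks=coarse_scene.landmarks,
            horizontal_plane=coarse_scene.horizontal_plane,
            side=coarse_scene.side,
            ground_truth=gt,
        )
        with pytest.raises(NoPatentForamenError):
            build_aperture(sealed)

    def test_scene_without_ground_truth_needs_explicit_canal(self, coarse_scene):
        bare = phantom.Scene(
            bone_mesh=coarse_scene.bone_mesh, cave_mesh=coarse_scene.cave_mesh,
            skin_mesh=coarse_scene.skin_mesh, landmarks=coarse_scene.landmarks,
            horizontal_plane=coarse_scene.horizontal_plane, side=coarse_scene.side,
        )
        with pytest.raises(ValueError, match="canal"):
            build_aperture(bare)
        gt = coarse_scene.ground_truth
        ap = build_aperture(bare, canal=(gt.fo_center, gt.fo_axis, gt.fo_canal_length))
        assert ap.area > 0

    def test_samples_lie_inside_rim_and_split_by_medial_plane(self, canonical_aperture):
        pts, medial = canonical_aperture.sample_points(1000, seed=0)
        assert 800 <= len(pts) <= 1250
        side = (pts - canonical_aperture.centroid) @ canonical_aperture.medial_dir
        assert np.array_equal(medial, side > 0)
        assert 0.3 < medial.mean() < 0.7  # roughly half the aperture each
        # all samples on the rim plane
        off = (pts - canonical_aperture.centroid) @ canonical_aperture.normal
        assert np.max(np.abs(off)) < 1e-9


class TestAssessEntryPoint:
    def test_axis_aligned_entry_is_easy(self, canonical_scene, canonical_aperture,
                                        canonical_context):
        p = entry_line_point(canonical_scene, -2.0, canonical_context)
        a = assess_entry_point(canonical_scene, canonical_aperture, p,
                               snap=False, context=canonical_context)
        assert a.accessible_fraction >= 0.5
        assert a.classification == "easy"
        assert not a.aperture_projection["slitlike"]

    def test_entry_behind_unbroken_plate_is_blocked(self, canonical_scene,
                                                    canonical_aperture, canonical_context):
        # from above the skull-base plate every ray to the aperture crosses bone
        a = assess_entry_point(canonical_scene, canonical_aperture,
                               np.array([0.0, -30.0, 40.0]),
                               snap=False, context=canonical_context)
        assert a.accessible_fraction == 0.0
        assert a.classification == "blocked"

    def test_entry_lateral_of_ramus_blocked_with_reason(self, canonical_scene,
                                                        canonical_aperture,
                                                        canonical_context):
        gt = canonical_scene.ground_truth
        skin_c, skin_n = gt.skin_plane()
        lateral = skin_c + np.array([8.0, 0.0, 0.0])
        lateral -= np.dot(lateral - skin_c, skin_n) * skin_n  # back onto the sheet
        assert lateral[0] > gt.ramus_anterior_x
        a = assess_entry_point(canonical_scene, canonical_aperture, lateral,
                               snap=False, context=canonical_context)
        assert a.classification == "blocked"
        assert a.reason == "mandible occlusion"

    def test_entry_inside_bone_rejected(self, canonical_scene, canonical_aperture,
                                        canonical_context):
        inside_plate = canonical_scene.ground_truth.fo_center + np.array([-12.0, 10.0, 0.0])
        with pytest.raises(EntryPointError, match="inside bone"):
            assess_entry_point(canonical_scene, canonical_aperture, inside_plate,
                               snap=False, context=canonical_context)

    def test_too_few_rays_rejected(self, canonical_scene, canonical_aperture,
                                   canonical_context):
        with pytest.raises(ValueError, match="n_rays"):
            assess_entry_point(canonical_scene, canonical_aperture,
                               np.zeros(3), n_rays=50, context=canonical_context)

    def test_fraction_converged_in_ray_count(self, canonical_scene, canonical_aperture,
                                             canonical_context):
        p = entry_line_point(canonical_scene, -2.0, canonical_context)
        f = {}
        for n in (500, 1000):
            f[n] = assess_entry_point(canonical_scene, canonical_aperture, p, n_rays=n,
                                      snap=False, context=canonical_context).accessible_fraction
        assert abs(f[500] - f[1000]) < 0.02

    def test_medial_half_dominates_low_in_the_easy_span(self, canonical_scene,
                                                        canonical_aperture,
                                                        canonical_context):
        # partial occlusion hides the lateral aperture first: aim medially
        for h in (-10.0, -7.0, -5.0):
            p = entry_line_point(canonical_scene, h, canonical_context)
            a = assess_entry_point(canonical_scene, canonical_aperture, p,
                                   snap=False, context=canonical_context)
            assert a.medial_fraction >= a.accessible_fraction

    def test_steep_view_projects_slitlike_aperture(self, closedform_scene,
                                                   closedform_aperture,
                                                   closedform_context):
        h_steep = closedform.slit_onset_height() + 3.0
        p = entry_line_point(closedform_scene, h_steep, closedform_context)
        a = assess_entry_point(closedform_scene, closedform_aperture, p,
                               snap=False, context=closedform_context)
        assert a.aperture_projection["slitlike"]
        assert a.aperture_projection["aspect_ratio"] > 3.0
        assert a.classification != "easy"


@pytest.fixture(scope="module")
def coarse_span(coarse_scene, coarse_aperture, coarse_context):
    return scan_entry_line(coarse_scene, coarse_aperture, n_rays=500,
                           context=coarse_context)


class TestScanEntryLine:
    def test_easy_span_contained_in_extreme_span(self, coarse_span):
        s = coarse_span
        assert s.lower_extreme <= s.lower_easy <= s.upper_easy <= s.upper_extreme

    def test_interior_easy_heights_classify_easy(self, coarse_scene, coarse_aperture,
                                                 coarse_context, coarse_span):
        lo, hi = coarse_span.lower_easy, coarse_span.upper_easy
        for f in (0.25, 0.5, 0.75):
            h = lo + f * (hi - lo)
            p = entry_line_point(coarse_scene, h, coarse_context)
            a = assess_entry_point(coarse_scene, coarse_aperture, p, n_rays=3000,
                                   snap=False, context=coarse_context)
            assert a.classification == "easy"

    def test_table_covers_grid_and_matches_classes(self, coarse_span):
        t = coarse_span.table
        assert len(t) == len(trajectory.DEFAULT_HEIGHTS)
        assert set(t["class"]) <= {"blocked", "possible", "easy"}
        assert (t.loc[t["fraction"] == 0.0, "class"] == "blocked").all()

    def test_mirrored_sides_give_identical_spans(self, coarse_scene, coarse_aperture,
                                                 coarse_context):
        left = generate_phantom(canonical_config(side="left", mesh_voxel_mm=0.7))
        ap_l = build_aperture(left)
        ctx_l = TrajectoryContext(left, ap_l)
        span_r = scan_entry_line(coarse_scene, coarse_aperture, n_rays=500,
                                 context=coarse_context)
        span_l = scan_entry_line(left, ap_l, n_rays=500, context=ctx_l)
        for name in ("lower_extreme", "upper_extreme", "lower_easy", "upper_easy"):
            assert getattr(span_l, name) == pytest.approx(getattr(span_r, name), abs=0.1)


class TestHartelAxis:
    @pytest.fixture
    def plane_skin_scene(self):
        """Minimal scene with a flat vertical cheek at y = -50."""
        skin = phantom._sheet_mesh(np.array([0.0, -50.0, -40.0]),
                                   np.array([0.0, -1.0, 0.0]), 200.0, 5.0)
        far = trimesh.creation.icosphere(subdivisions=1, radius=1.0)
        far.apply_translation([200.0, 200.0, 200.0])
        scene = phantom.Scene(
            bone_mesh=far, cave_mesh=far.copy(), skin_mesh=skin,
            landmarks={
                "impression_point": np.array([0.0, 0.0, 0.0]),
                "mouth_angle": np.array([0.0, -50.0, -50.0]),
                "fiducial_1": np.array([5.0, 0.0, 10.0]),
                "fiducial_2": np.array([-5.0, 0.0, 10.0]),
                "fiducial_3": np.array([0.0, 5.0, 12.0]),
            },
            horizontal_plane=HorizontalPlane(np.array([0.0, -50.0, -50.0]),
                                             np.array([0.0, 0.0, 1.0])),
            side="right",
        )
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        normal = np.array([0.0, -1.0, -1.0]) / np.sqrt(2)
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.cross(normal, e1)
        centroid = np.array([0.0, -10.0, -10.0])
        rim = centroid + 2.0 * (np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2)
        aperture = ApertureModel(
            rim_points=rim, centroid=centroid, normal=normal, area=np.pi * 4.0,
            ellipse_axes=(2.0, 2.0), ellipse_dirs=np.stack([e1, e2]),
            medial_dir=-e1, canal_length=10.0, side="right",
        )
        return scene, aperture

    def test_matches_analytic_line_plane_intersection(self, plane_skin_scene):
        scene, aperture = plane_skin_scene
        hx = hartel_axis(scene, aperture)
        assert np.allclose(hx.einstichpunkt, [0.0, -50.0, -50.0], atol=1e-6)
        assert hx.einstich_height == pytest.approx(0.0, abs=1e-6)
        # collinearity of origin, FO centre, exit
        d1 = hx.axis_through - hx.axis_origin
        d2 = hx.einstichpunkt - hx.axis_origin
        assert np.linalg.norm(np.cross(d1, d2)) / np.linalg.norm(d2) < 1e-6

    def test_raising_origin_strictly_lowers_exit(self, plane_skin_scene):
        scene, aperture = plane_skin_scene
        heights = [
            hartel_axis(scene, aperture,
                        origin_offset=dz * scene.horizontal_plane.normal).einstich_height
            for dz in (0.0, 1.0, 2.0)
        ]
        assert heights[0] > heights[1] > heights[2]

    def test_exit_on_canonical_phantom_lies_on_skin_sheet(self, canonical_scene,
                                                          canonical_aperture,
                                                          canonical_context):
        hx = hartel_axis(canonical_scene, canonical_aperture, context=canonical_context)
        skin_c, skin_n = canonical_scene.ground_truth.skin_plane()
        assert abs(np.dot(hx.einstichpunkt - skin_c, skin_n)) < 1e-6

    def test_invariant_under_joint_rigid_motion(self, coarse_scene, coarse_aperture,
                                                coarse_context):
        h0 = hartel_axis(coarse_scene, coarse_aperture, context=coarse_context).einstich_height
        T = RigidTransform.from_rotvec([25, -10, 40], [30.0, -12.0, 8.0])
        moved = coarse_scene.transformed(T)
        ap = build_aperture(moved)
        h1 = hartel_axis(moved, ap).einstich_height
        assert h1 == pytest.approx(h0, abs=1e-6)

    def test_missing_skin_raises(self, plane_skin_scene):
        scene, aperture = plane_skin_scene
        tiny = phantom._sheet_mesh(np.array([500.0, -50.0, 0.0]),
                                   np.array([0.0, -1.0, 0.0]), 5.0, 2.5)
        broken = phantom.Scene(
            bone_mesh=scene.bone_mesh, cave_mesh=scene.cave_mesh, skin_mesh=tiny,
            landmarks=scene.landmarks, horizontal_plane=scene.horizontal_plane,
            side="right",
        )
        with pytest.raises(RuntimeError, match="skin"):
            hartel_axis(broken, aperture)


class TestRecommendEntry:
    def span(self, lo_easy, hi_easy):
        table = pd.DataFrame(
            {"height_mm": [-10.0, -2.0, 5.0], "fraction": [0.2, 0.8, 0.4]}
        )
        return SpanResult(
            lower_extreme=-20.0, upper_extreme=15.0,
            lower_easy=lo_easy, upper_easy=hi_easy,
            side="right", table=table,
        )

    def test_target_height_inside_easy_span(self):
        assert recommend_entry(self.span(-8.0, 5.0)).height == pytest.approx(-2.0)

    def test_soft_tissue_offset_lowers_recommendation(self):
        rec = recommend_entry(self.span(-8.0, 5.0), soft_tissue_offset=5.0)
        assert rec.height == pytest.approx(-7.0)
        assert not rec.downgraded

    def test_target_clamped_into_easy_span(self):
        assert recommend_entry(self.span(3.0, 10.0)).height == pytest.approx(3.0)

    def test_downgrade_to_best_possible_without_easy_span(self):
        rec = recommend_entry(self.span(None, None))
        assert rec.downgraded
        assert rec.height == pytest.approx(-2.0)  # max-fraction row
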