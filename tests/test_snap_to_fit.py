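import numpy as np
import pytest

import fragreduce as fr
from fragreduce.core_geometry import RigidTransform, compose, rotation_angle_between, transforms_close
from fragreduce.snap_to_fit import (
    MarkedSurface,
    SnapParams,
    attraction_wrench,
    colinearity_weight,
    paint_surface,
    snap_to_fit,
)
from fragreduce.surface_model import DistanceField, Fragment, PointShell

from conftest import coarse_start


def _planar_pair(n_side=6, gap=2.0, flip_target_normals=False):
    """Two parallel planar marked faces with opposing outward normals."""
    xs, ys = np.meshgrid(np.arange(n_side, dtype=float), np.arange(n_side, dtype=float))
    pts_m = np.column_stack([np.zeros(n_side**2), xs.ravel(), ys.ravel()])
    pts_t = pts_m + np.array([gap, 0.0, 0.0])
    n_m = np.tile([1.0, 0.0, 0.0], (len(pts_m), 1))       # moving face points +x
    sign = 1.0 if flip_target_normals else -1.0
    n_t = np.tile([sign, 0.0, 0.0], (len(pts_t), 1))      # target face points -x (mating)
    vals = np.full((3, 3, 3), 10.0)  # inert far-away field: no contact anywhere

    def frag(label, pts, nrm, far):
        field = DistanceField(vals, np.ones(3), far)
        return Fragment(label=label, shell=PointShell(pts, nrm, np.arange(len(pts))), field=field)

    moving = frag(1, pts_m, n_m, np.array([500.0, 500.0, 500.0]))
    target = frag(2, pts_t, n_t, np.array([600.0, 600.0, 600.0]))
    mark_m = MarkedSurface(1, np.arange(len(pts_m)))
    mark_t = MarkedSurface(2, np.arange(len(pts_t)))
    return moving, mark_m, target, mark_t


class TestPainting:
    def test_path_far_from_fragment_marks_nothing(self, phantom_one_cut):
        _, frags = phantom_one_cut
        frag = frags[min(frags)]
        ms = paint_surface(frag, [[500.0, 500.0, 500.0]], brush_radius=2.0)
        assert len(ms) == 0

    def test_brush_covering_everything_marks_all_points(self, phantom_one_cut):
        _, frags = phantom_one_cut
        frag = frags[min(frags)]
        center = frag.world_centroid
        ms = paint_surface(frag, [center], brush_radius=1000.0)
        np.testing.assert_array_equal(ms.marked_ids, np.sort(frag.shell.point_ids))

    def test_painting_matches_brute_force_distance_filter(self, phantom_one_cut):
        _, frags = phantom_one_cut
        frag = frags[min(frags)]
        rng = np.random.default_rng(0)
        lo, hi = frag.field.bounds()
        path = rng.uniform(lo, hi, size=(5, 3))
        r = 3.0
        ms = paint_surface(frag, path, brush_radius=r)
        d = np.min(
            np.linalg.norm(frag.world_shell_points()[:, None] - path[None], axis=-1), axis=1
        )
        expected = np.sort(frag.shell.point_ids[d <= r])
        np.testing.assert_array_equal(ms.marked_ids, expected)

    def test_painting_is_cumulative_and_idempotent(self, phantom_one_cut):
        _, frags = phantom_one_cut
        frag = frags[min(frags)]
        p1 = frag.world_shell_points()[0]
        p2 = frag.world_shell_points()[-1]
        a = paint_surface(frag, [p1], brush_radius=2.0)
        again = paint_surface(frag, [p1], brush_radius=2.0, existing=a)
        np.testing.assert_array_equal(a.marked_ids, again.marked_ids)
        both = paint_surface(frag, [p2], brush_radius=2.0, existing=a)
        expected = np.union1d(a.marked_ids, paint_surface(frag, [p2], 2.0).marked_ids)
        np.testing.assert_array_equal(both.marked_ids, expected)


class TestColinearityWeight:
    def test_opposing_normals_score_one(self):
        assert colinearity_weight([0, 0, 1.0], [0, 0, -1.0]) == pytest.approx(1.0)

    def test_identical_normals_score_zero(self):
        assert colinearity_weight([0, 0, 1.0], [0, 0, 1.0]) == 0.0

    def test_perpendicular_normals_score_zero(self):
        assert colinearity_weight([1.0, 0, 0], [0, 1.0, 0]) == 0.0

    def test_exponent_sharpens_partial_alignment(self):
        n1, n2 = np.array([0, 0, 1.0]), np.array([0, np.sin(0.5), -np.cos(0.5)])
        w1 = colinearity_weight(n1, n2, 1.0)
        w2 = colinearity_weight(n1, n2, 2.0)
        assert 0 < w2 < w1 < 1


class TestAttractionWrench:
    def test_empty_markings_give_zero_wrench(self, phantom_one_cut):
        _, frags = phantom_one_cut
        labels = sorted(frags)
        empty = MarkedSurface(labels[0], np.empty(0, np.int64))
        other = MarkedSurface(labels[1], frags[labels[1]].shell.point_ids[:10])
        w, sim, n = attraction_wrench(
            frags[labels[0]], empty, frags[labels[1]], other, SnapParams()
        )
        assert sim == 0.0 and n == 0
        np.testing.assert_array_equal(w.force, 0)

    def test_planar_pair_closed_form_force_and_zero_torque(self):
        gap = 2.0
        moving, mm, target, tm = _planar_pair(gap=gap)
        sp = SnapParams(k_a=1.5, capture_radius=5.0)
        w, sim, n = attraction_wrench(moving, mm, target, tm, sp)
        assert n == len(mm)
        assert sim == pytest.approx(1.0)
        np.testing.assert_allclose(w.force, [sp.k_a * n * gap, 0, 0], atol=1e-9)
        np.testing.assert_allclose(w.torque, 0, atol=1e-9)

    def test_same_direction_normals_give_zero_wrench(self):
        moving, mm, target, tm = _planar_pair(flip_target_normals=True)
        w, sim, n = attraction_wrench(moving, mm, target, tm, SnapParams())
        assert sim == 0.0
        np.testing.assert_allclose(w.force, 0, atol=1e-12)

    def test_pairs_beyond_capture_radius_contribute_nothing(self):
        moving, mm, target, tm = _planar_pair(gap=10.0)
        w, sim, n = attraction_wrench(moving, mm, target, tm, SnapParams(capture_radius=5.0))
        assert n == 0 and sim == 0.0
        np.testing.assert_array_equal(w.force, 0)


class TestSnap:
    def test_start_at_mating_pose_is_a_fixed_point(self, phantom_one_cut):
        pt, frags = phantom_one_cut
        ma, mb = fr.fracture_face_markings(pt, frags)[0]
        a, b = ma.fragment_label, mb.fragment_label
        moving, target = frags[b], frags[a]
        target.pose = pt.truth_poses[a]
        res = snap_to_fit(moving, mb, target, ma, pt.truth_poses[b], SnapParams())
        assert res.converged
        err_t = np.linalg.norm(
            res.final_pose.apply(moving.centroid) - pt.truth_poses[b].apply(moving.centroid)
        )
        assert err_t <= 0.35  # stays at the fit (sub-voxel equilibrium shift)
        moving.pose = RigidTransform.identity()
        target.pose = RigidTransform.identity()

    def test_recovers_ground_truth_from_coarse_start(self, phantom_one_cut):
        pt, frags = phantom_one_cut
        ma, mb = fr.fracture_face_markings(pt, frags)[0]
        a, b = ma.fragment_label, mb.fragment_label
        moving, target = frags[b], frags[a]
        target.pose = pt.truth_poses[a]
        truth = pt.truth_poses[b]
        start = coarse_start(truth, moving.centroid, np.random.default_rng(1), mm=2.0, deg=5.0)
        res = snap_to_fit(moving, mb, target, ma, start, SnapParams())
        assert res.converged
        err_t = np.linalg.norm(res.final_pose.apply(moving.centroid) - truth.apply(moving.centroid))
        err_r = np.degrees(rotation_angle_between(res.final_pose, truth))
        assert err_t <= 0.5 and err_r <= 1.0
        moving.pose = RigidTransform.identity()
        target.pose = RigidTransform.identity()

    def test_final_pose_is_a_stable_equilibrium_under_perturbation(self, phantom_one_cut):
        pt, frags = phantom_one_cut
        ma, mb = fr.fracture_face_markings(pt, frags)[0]
        a, b = ma.fragment_label, mb.fragment_label
        moving, target = frags[b], frags[a]
        target.pose = pt.truth_poses[a]
        truth = pt.truth_poses[b]
        res = snap_to_fit(moving, mb, target, ma, truth, SnapParams())
        rng = np.random.default_rng(3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        nudge = compose(
            RigidTransform(translation=0.1 * axis),
            RigidTransform.from_axis_angle(axis, np.radians(0.5)),
        )
        res2 = snap_to_fit(moving, mb, target, ma, compose(nudge, res.final_pose), SnapParams())
        d = np.linalg.norm(
            res2.final_pose.apply(moving.centroid) - res.final_pose.apply(moving.centroid)
        )
        ang = np.degrees(rotation_angle_between(res2.final_pose, res.final_pose))
        assert d <= 0.1 and ang <= 0.5
        moving.pose = RigidTransform.identity()
        target.pose = RigidTransform.identity()

    def test_damaged_faces_converge_with_lower_similarity(self):
        seed = 6
        def run(erosion):
            pt = fr.generate_phantom(fr.PhantomSpec(seed=seed, n_cuts=1, erosion_voxels=erosion))
            frags = fr.build_fragments(pt.labeled)
            ma, mb = fr.fracture_face_markings(pt, frags)[0]
            a, b = ma.fragment_label, mb.fragment_label
            frags[a].pose = pt.truth_poses[a]
            start = coarse_start(
                pt.truth_poses[b], frags[b].centroid, np.random.default_rng(seed), mm=2.0, deg=5.0
            )
            return snap_to_fit(frags[b], mb, frags[a], ma, start, SnapParams())

        intact = run(0)
        eroded = run(2)
        assert intact.converged and eroded.converged
        assert eroded.similarity < intact.similarity

    def test_start_outside_capture_distance_reports_no_pairs(self, phantom_one_cut):
        pt, frags = phantom_one_cut
        ma, mb = fr.fracture_face_markings(pt, frags)[0]
        a, b = ma.fragment_label, mb.fragment_label
        moving, target = frags[b], frags[a]
        target.pose = pt.truth_poses[a]
        far = compose(RigidTransform(translation=np.array([200.0, 0, 0])), pt.truth_poses[b])
        res = snap_to_fit(moving, mb, target, ma, far, SnapParams())
        assert not res.converged and res.n_pairs == 0
        moving.pose = RigidTransform.identity()
        target.pose = RigidTransform.identity()


def _two_site_scene():
    """A bracket with two identical mating sites and a cube that fits either."""
    lab = np.zeros((70, 30, 24), dtype=np.int32)
    lab[2:16, 2:28, 2:22] = 1     # left slab
    lab[50:64, 2:28, 2:22] = 1    # right slab
    lab[2:64, 2:6, 2:22] = 1      # back bar joins them: one connected bracket
    lab[20:46, 8:26, 4:20] = 2    # moving cube between the two inner faces
    lv = fr.LabeledVolume(lab, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    frags = fr.build_fragments(lv)
    bracket, cube = frags[1], frags[2]
    # mark the LEFT site only: cube's -x face and the bracket's left inner face
    cube_pts = cube.shell.points
    mark_cube = MarkedSurface(2, cube.shell.point_ids[np.abs(cube_pts[:, 0] - 20.0) < 0.7])
    br_pts = bracket.shell.points
    inner_left = (np.abs(br_pts[:, 0] - 16.0) < 0.7) & (br_pts[:, 1] > 7.0)
    mark_bracket = MarkedSurface(1, bracket.shell.point_ids[inner_left])
    assert len(mark_cube) > 50 and len(mark_bracket) > 50
    return lv, bracket, cube, mark_bracket, mark_cube


class TestMarkingRestriction:
    def test_snap_goes_to_the_marked_site_from_all_starts(self):
        lv, bracket, cube, mark_bracket, mark_cube = _two_site_scene()
        rng = np.random.default_rng(0)
        for _ in range(6):
            # keep the marked faces inside the 5 mm capture radius (gap is 4 mm)
            start = RigidTransform(
                translation=np.array([rng.uniform(-1.5, 0.8), *rng.uniform(-1.5, 1.5, 2)])
            )
            res = snap_to_fit(cube, mark_cube, bracket, mark_bracket, start, SnapParams())
            # marked (left) site closes the 4 mm gap: x -> -4; right site would be +4
            assert res.final_pose.translation[0] == pytest.approx(-4.0, abs=1.0)
            cube.pose = RigidTransform.identity()

    def test_result_invariant_to_geometry_edits_outside_marked_neighborhood(self):
        lv, bracket, cube, mark_bracket, mark_cube = _two_site_scene()
        start = RigidTransform(translation=np.array([0.5, -0.4, 0.3]))
        res_a = snap_to_fit(cube, mark_cube, bracket, mark_bracket, start, SnapParams())
        cube.pose = RigidTransform.identity()

        # mutate the cube's far (+x) face shell points: push them outward a bit
        far = cube.shell.points[:, 0] > 44.0
        assert far.sum() > 50
        cube.shell.points[far] += np.array([1.0, 0.0, 0.0])
        res_b = snap_to_fit(cube, mark_cube, bracket, mark_bracket, start, SnapParams())
        assert transforms_close(res_b.final_pose, res_a.final_pose, atol_t=0.05, atol_q=1e-4)
        assert res_b.similarity == pytest.approx(res_a.similarity, abs=1e-4)
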