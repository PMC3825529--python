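import numpy as np
import pytest

import fragreduce as fr
from fragreduce.contact_dynamics import (
    CouplingParams,
    HandleTrajectory,
    contact_wrench,
    coupling_wrench,
    simulate_manipulation,
    step_quasistatic,
)
from fragreduce.core_geometry import RigidTransform, compose, transforms_close
from fragreduce.surface_model import DistanceField, Fragment, PointShell

from conftest import random_rigid


def _half_space_fragment(label=1, extent=30, normal_axis=0):
    """A thick slab whose field is an exact analytic half-space below x=0."""
    n = extent
    vals = np.zeros((n, n, n))
    idx = np.indices((n, n, n))
    # field origin chosen so the surface (value 0) sits at x = 0
    origin = np.array([-(n - 5) * 1.0, -n / 2, -n / 2])
    vals = (idx[normal_axis] + 0.5) * 1.0 + origin[normal_axis]
    pts = np.array([[0.0, 0.0, 0.0]])
    nrm = np.zeros((1, 3))
    nrm[0, normal_axis] = 1.0
    shell = PointShell(pts, nrm, np.array([0]))
    field = DistanceField(vals, np.ones(3), origin)
    return Fragment(label=label, shell=shell, field=field)


def _point_fragment(label=2, at=(0.0, 0.0, 0.0)):
    """A fragment that is a single shell point (its own tiny field)."""
    vals = np.full((3, 3, 3), 1.0)
    vals[1, 1, 1] = -0.5
    shell = PointShell(np.array([list(at)]), np.array([[1.0, 0, 0]]), np.array([7]))
    field = DistanceField(vals, np.ones(3), np.asarray(at) - 1.5)
    return Fragment(label=label, shell=shell, field=field, centroid=np.asarray(at, float))


class TestContactWrench:
    def test_separated_fragments_have_zero_wrench(self, wall_cube_fragments):
        wall, cube = wall_cube_fragments[1], wall_cube_fragments[2]
        res = contact_wrench(cube, [wall])
        assert res.contacts == []
        assert res.max_penetration == 0.0
        np.testing.assert_array_equal(res.wrench.force, 0)
        np.testing.assert_array_equal(res.wrench.torque, 0)

    def test_single_point_in_half_space_gives_closed_form_force(self):
        wall = _half_space_fragment()
        depth = 0.8
        probe = _point_fragment(at=(-depth, 0.0, 0.0))
        k_c = 50.0
        res = contact_wrench(probe, [wall], k_c=k_c)
        assert len(res.contacts) == 1
        assert res.max_penetration == pytest.approx(depth, abs=1e-9)
        np.testing.assert_allclose(res.wrench.force, [k_c * depth, 0, 0], atol=1e-9)
        np.testing.assert_allclose(res.wrench.torque, 0, atol=1e-9)

    def test_pruning_never_changes_result_on_random_poses(self, phantom_one_cut):
        pt, frags = phantom_one_cut
        labels = sorted(frags)
        moving, static = frags[labels[1]], frags[labels[0]]
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(30):
            moving.pose = random_rigid(rng, max_t=4.0)
            pruned = contact_wrench(moving, [static], use_pruning=True)
            brute = contact_wrench(moving, [static], use_pruning=False)
            np.testing.assert_allclose(pruned.wrench.force, brute.wrench.force, atol=1e-9)
            np.testing.assert_allclose(pruned.wrench.torque, brute.wrench.torque, atol=1e-9)
            assert [c.point_id for c in pruned.contacts] == [c.point_id for c in brute.contacts]
            hits += bool(pruned.contacts)
        assert hits > 0  # the sweep must actually produce contact states
        moving.pose = RigidTransform.identity()

    def test_moving_fragment_rejected_in_static_list(self, wall_cube_fragments):
        cube = wall_cube_fragments[2]
        with pytest.raises(ValueError):
            contact_wrench(cube, [cube])


class TestCouplingWrench:
    def test_coincident_poses_give_zero_wrench(self):
        p = CouplingParams()
        t = random_rigid(np.random.default_rng(0))
        w = coupling_wrench(t, t, p)
        np.testing.assert_allclose(w.force, 0, atol=1e-12)
        np.testing.assert_allclose(w.torque, 0, atol=1e-12)

    def test_pure_offset_gives_spring_force_toward_handle(self):
        p = CouplingParams(k_t=2.5)
        frag = RigidTransform.identity()
        handle = RigidTransform(translation=np.array([2.0, 0.0, 0.0]))
        w = coupling_wrench(handle, frag, p)
        np.testing.assert_allclose(w.force, [2.5 * 2.0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(w.torque, 0, atol=1e-12)

    def test_quarter_turn_gives_k_r_half_pi_torque_along_axis(self):
        p = CouplingParams(k_r=40.0)
        frag = RigidTransform.identity()
        handle = RigidTransform.from_axis_angle([0, 0, 1], np.pi / 2)
        w = coupling_wrench(handle, frag, p)
        np.testing.assert_allclose(w.torque, [0, 0, 40.0 * np.pi / 2], atol=1e-9)
        np.testing.assert_allclose(w.force, 0, atol=1e-12)


class TestQuasistaticStep:
    def test_free_space_converges_to_handle_pose(self, wall_cube_fragments):
        cube = wall_cube_fragments[2]
        wall = wall_cube_fragments[1]
        p = CouplingParams()
        handle = RigidTransform.from_axis_angle(
            [0, 1, 0], 0.4, translation=np.array([4.0, 1.0, -2.0])
        )
        res = step_quasistatic(handle, cube, [wall], p)
        assert res.converged
        assert transforms_close(res.pose, handle, atol_t=5 * p.tol, atol_q=5 * p.tol)
        cube.pose = RigidTransform.identity()

    def test_wall_press_respects_spring_penalty_penetration_bound(self, wall_cube_volume):
        frags = fr.build_fragments(wall_cube_volume)
        wall, cube = frags[1], frags[2]
        p = CouplingParams()
        D = 5.0  # handle pushed 5 mm past first contact (cube face 20 -> wall face 8)
        samples = [
            (float(t), RigidTransform(translation=np.array([-x, 0.0, 0.0])))
            for t, x in enumerate(np.linspace(0, 12 + D, 30))
        ]
        poses, log = simulate_manipulation(HandleTrajectory(samples), cube, [wall], p)
        bound = p.k_t * D / p.k_c + np.linalg.norm(wall_cube_volume.spacing)
        assert log.max_penetration <= bound
        # the fragment rests at the wall: face position 8 +- a small penalty depth
        assert poses[-1].translation[0] == pytest.approx(-12.0, abs=0.25)
        # 1-D closed form: equilibrium total force is zero; with n identical
        # contacts at depth d, k_t * stretch = n * k_c * d
        last = log.steps[-1]
        n_c = last["n_contacts"]
        stretch = abs(-(12 + D) - poses[-1].translation[0])
        d_pred = p.k_t * stretch / (n_c * p.k_c)
        assert last["max_penetration"] <= d_pred + np.linalg.norm(wall_cube_volume.spacing)

    def test_sliding_handle_keeps_penetration_bounded(self, wall_cube_volume):
        frags = fr.build_fragments(wall_cube_volume)
        wall, cube = frags[1], frags[2]
        p = CouplingParams()
        D = 3.0
        press = [(-x, 0.0) for x in np.linspace(0, 12 + D, 15)]
        slide = [(-(12 + D), y) for y in np.linspace(0.0, 2.0, 10)]
        samples = [
            (float(i), RigidTransform(translation=np.array([x, y, 0.0])))
            for i, (x, y) in enumerate(press + slide)
        ]
        poses, log = simulate_manipulation(HandleTrajectory(samples), cube, [wall], p)
        bound = p.k_t * D / p.k_c + np.linalg.norm(wall_cube_volume.spacing)
        assert log.max_penetration <= bound
        # tangential tracking: y follows the handle (edge-gradient tilt allows
        # a small frictionless drift)
        assert poses[-1].translation[1] == pytest.approx(2.0, abs=0.3)

    def test_contact_force_monotone_while_handle_advances(self, wall_cube_volume):
        frags = fr.build_fragments(wall_cube_volume)
        wall, cube = frags[1], frags[2]
        samples = [
            (float(t), RigidTransform(translation=np.array([-x, 0.0, 0.0])))
            for t, x in enumerate(np.linspace(0, 16, 25))
        ]
        _, log = simulate_manipulation(HandleTrajectory(samples), cube, [wall], CouplingParams())
        forces = [s["force_norm"] for s in log.steps]
        assert all(b >= a - 1e-9 for a, b in zip(forces, forces[1:]))

    def test_identical_runs_are_bitwise_identical(self, wall_cube_volume):
        def run():
            frags = fr.build_fragments(wall_cube_volume)
            samples = [
                (float(t), RigidTransform(translation=np.array([-x, 0.2 * x, 0.0])))
                for t, x in enumerate(np.linspace(0, 14, 12))
            ]
            return simulate_manipulation(
                HandleTrajectory(samples), frags[2], [frags[1]], CouplingParams()
            )[1]

        a, b = run(), run()
        assert a.steps == b.steps

    def test_stationary_free_trajectory_ends_at_handle(self, wall_cube_volume):
        frags = fr.build_fragments(wall_cube_volume)
        handle = RigidTransform(translation=np.array([2.0, 0.0, 1.0]))
        traj = HandleTrajectory([(0.0, handle), (1.0, handle), (2.0, handle)])
        poses, log = simulate_manipulation(traj, frags[2], [frags[1]], CouplingParams())
        assert transforms_close(poses[-1], handle, atol_t=1e-3, atol_q=1e-3)

    def test_step_is_equivariant_under_rigid_scene_motion(self, wall_cube_volume):
        rng = np.random.default_rng(5)
        G = random_rigid(rng, max_t=15.0)
        p = CouplingParams()
        handle = RigidTransform(translation=np.array([-13.0, 0.5, -0.5]))

        frags1 = fr.build_fragments(wall_cube_volume)
        res1 = step_quasistatic(handle, frags1[2], [frags1[1]], p)

        frags2 = fr.build_fragments(wall_cube_volume)
        frags2[1].pose = compose(G, frags2[1].pose)
        frags2[2].pose = compose(G, frags2[2].pose)
        res2 = step_quasistatic(compose(G, handle), frags2[2], [frags2[1]], p)

        assert transforms_close(res2.pose, compose(G, res1.pose), atol_t=1e-6, atol_q=1e-6)

    def test_trajectory_times_must_increase(self):
        with pytest.raises(ValueError):
            HandleTrajectory([(0.0, RigidTransform.identity()), (0.0, RigidTransform.identity())])

    def test_trajectory_json_roundtrip(self):
        rng = np.random.default_rng(8)
        traj = HandleTrajectory([(0.0, random_rigid(rng)), (0.5, random_rigid(rng))])
        back = HandleTrajectory.from_json(traj.to_json())
        for (t0, p0), (t1, p1) in zip(traj.samples, back.samples):
            assert t0 == t1 and transforms_close(p0, p1, 1e-12, 1e-12)
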