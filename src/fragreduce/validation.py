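"""Scenario studies quantifying the toolkit's behavioral contracts.

Each function builds its own inputs from the phantom generator (or a simple
constructed scene), runs the relevant pipeline, and returns measured
quantities: penetration bounds under wall-press scripts, snap-to-fit pose
recovery rates, marked-site selectivity, grouping exactness, and the
end-to-end closure from raw intensity volume to a scored reconstruction plan.
"""

from __future__ import annotations

import numpy as np

from .assembly import Scene, attach, create_group, reduction_report, set_group_pose
from .contact_dynamics import (
    CouplingParams,
    HandleTrajectory,
    contact_wrench,
    simulate_manipulation,
    step_quasistatic,
)
from .core_geometry import RigidTransform, compose, rotation_angle_between
from .phantom_generator import (
    PhantomSpec,
    fracture_face_markings,
    generate_phantom,
    intensity_volume,
)
from .snap_to_fit import MarkedSurface, SnapParams, snap_to_fit
from .surface_model import build_fragments
from .volume_segmentation import LabeledVolume, segment_fragments


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def offset_pose(truth: RigidTransform, centroid, rng, mm: float, deg: float) -> RigidTransform:
    """A pose whose error vs truth is exactly (mm, deg), measured at the centroid."""
    c_truth = truth.apply(centroid)
    rot = RigidTransform.from_axis_angle(_unit(rng), np.radians(deg))
    about = RigidTransform(rot.quaternion, c_truth - rot.rotate_vectors(c_truth))
    shift = RigidTransform(translation=mm * _unit(rng))
    return compose(shift, compose(about, truth))


def wall_press_study(press_depth: float = 5.0, cp: CouplingParams | None = None) -> dict:
    """Press a cube 5 mm past a wall, then slide along it.

    Returns the worst penetration over both scripts, the spring/penalty bound
    k_t*D/k_c + one voxel diagonal, and the free-space tracking error.
    """
    cp = cp or CouplingParams()
    lab = np.zeros((40, 20, 20), dtype=np.int32)
    lab[2:8, 2:18, 2:18] = 1
    lab[20:30, 5:15, 5:15] = 2
    lv = LabeledVolume(lab, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    frags = build_fragments(lv)
    wall, cube = frags[1], frags[2]
    diag = float(np.linalg.norm(lv.spacing))

    # free-space tracking
    handle = RigidTransform.from_axis_angle([0, 1, 0], 0.3, translation=[4.0, 1.0, -2.0])
    free = step_quasistatic(handle, cube, [wall], cp)
    free_err = float(np.linalg.norm(free.pose.translation - handle.translation))

    cube.pose = RigidTransform.identity()
    D = press_depth
    press = [(-x, 0.0) for x in np.linspace(0, 12 + D, 25)]
    slide = [(-(12 + D), y) for y in np.linspace(0.0, 2.0, 10)]
    samples = [
        (float(i), RigidTransform(translation=np.array([x, y, 0.0])))
        for i, (x, y) in enumerate(press + slide)
    ]
    _, log = simulate_manipulation(HandleTrajectory(samples), cube, [wall], cp)
    bound = cp.k_t * D / cp.k_c + diag
    return {
        "max_penetration_mm": float(log.max_penetration),
        "penetration_bound_mm": float(bound),
        "free_space_tracking_error_mm": free_err,
        "n_steps": len(log.steps),
    }


def collision_pruning_study(n_poses: int = 100, seed: int = 0) -> dict:
    """Hierarchically pruned vs exhaustive contact wrench on random poses."""
    pt = generate_phantom(PhantomSpec(seed=seed, n_cuts=1, volume_shape=(32, 32, 32)))
    frags = build_fragments(pt.labeled)
    labels = sorted(frags)
    moving, static = frags[labels[-1]], frags[labels[0]]
    rng = np.random.default_rng(seed + 1)
    # draw translations that interpolate toward the static fragment so a good
    # share of poses genuinely overlap
    c_m, c_s = moving.world_centroid, static.world_centroid
    max_diff = 0.0
    mismatches = 0
    hits = 0
    for _ in range(n_poses):
        rot = RigidTransform.from_axis_angle(_unit(rng), rng.uniform(0, np.pi))
        # place the rotated centroid somewhere between the two fragments
        target_c = c_m + rng.uniform(0.0, 1.2) * (c_s - c_m) + rng.uniform(-3, 3, size=3)
        t = target_c - rot.rotate_vectors(moving.centroid)
        moving.pose = RigidTransform(rot.quaternion, t)
        pruned = contact_wrench(moving, [static], use_pruning=True)
        brute = contact_wrench(moving, [static], use_pruning=False)
        max_diff = max(
            max_diff,
            float(np.max(np.abs(pruned.wrench.force - brute.wrench.force))),
            float(np.max(np.abs(pruned.wrench.torque - brute.wrench.torque))),
        )
        if [c.point_id for c in pruned.contacts] != [c.point_id for c in brute.contacts]:
            mismatches += 1
        hits += bool(pruned.contacts)
    return {
        "n_poses": n_poses,
        "n_poses_in_contact": hits,
        "max_wrench_difference": max_diff,
        "n_contact_set_mismatches": mismatches,
    }


def _snap_one(pt, frags, pair, rng, sp=None, start_mm=2.0, start_deg=5.0):
    """Snap the second fragment of a mating pair onto the first (at truth)."""
    ma, mb = pair
    a, b = ma.fragment_label, mb.fragment_label
    moving, target = frags[b], frags[a]
    target.pose = pt.truth_poses[a]
    truth = pt.truth_poses[b]
    start = offset_pose(truth, moving.centroid, rng, start_mm, start_deg)
    res = snap_to_fit(moving, mb, target, ma, start, sp or SnapParams())
    err_t = float(np.linalg.norm(res.final_pose.apply(moving.centroid) - truth.apply(moving.centroid)))
    err_r = float(np.degrees(rotation_angle_between(res.final_pose, truth)))
    moving.pose = RigidTransform.identity()
    target.pose = RigidTransform.identity()
    return err_t, err_r, res


def snap_recovery_study(
    n_phantoms: int = 20,
    seed: int = 0,
    n_eroded: int = 5,
    tol_mm: float = 0.5,
    tol_deg: float = 1.0,
) -> dict:
    """Pose recovery from (2 mm, 5°) starts on seeded phantoms.

    Also re-runs the first ``n_eroded`` phantoms with compression-fracture
    face damage and counts how often the damaged-face similarity drops below
    the intact-face similarity of the same phantom.
    """
    recovered = 0
    errs = []
    sims = {}
    for i in range(n_phantoms):
        ph_seed = seed * 1000 + i
        pt = generate_phantom(PhantomSpec(seed=ph_seed, n_cuts=1))
        frags = build_fragments(pt.labeled)
        pair = fracture_face_markings(pt, frags)[0]
        rng = np.random.default_rng(ph_seed + 17)
        err_t, err_r, res = _snap_one(pt, frags, pair, rng)
        errs.append((err_t, err_r))
        sims[i] = res.similarity
        if err_t <= tol_mm and err_r <= tol_deg:
            recovered += 1
    eroded_lower = 0
    eroded_converged = 0
    for i in range(n_eroded):
        ph_seed = seed * 1000 + i
        pt = generate_phantom(PhantomSpec(seed=ph_seed, n_cuts=1, erosion_voxels=2))
        frags = build_fragments(pt.labeled)
        pair = fracture_face_markings(pt, frags)[0]
        rng = np.random.default_rng(ph_seed + 17)
        _, _, res = _snap_one(pt, frags, pair, rng)
        eroded_converged += bool(res.converged)
        eroded_lower += bool(res.similarity < sims[i])
    errs = np.asarray(errs)
    return {
        "n_phantoms": n_phantoms,
        "recovery_rate_percent": 100.0 * recovered / n_phantoms,
        "median_translation_error_mm": float(np.median(errs[:, 0])),
        "median_rotation_error_deg": float(np.median(errs[:, 1])),
        "n_eroded": n_eroded,
        "eroded_similarity_lower_percent": 100.0 * eroded_lower / max(n_eroded, 1),
        "eroded_converged_percent": 100.0 * eroded_converged / max(n_eroded, 1),
    }


def two_site_scene():
    """A bracket with two identical mating sites; only the left one is marked."""
    lab = np.zeros((70, 30, 24), dtype=np.int32)
    lab[2:16, 2:28, 2:22] = 1
    lab[50:64, 2:28, 2:22] = 1
    lab[2:64, 2:6, 2:22] = 1
    lab[20:46, 8:26, 4:20] = 2
    lv = LabeledVolume(lab, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    frags = build_fragments(lv)
    bracket, cube = frags[1], frags[2]
    mark_cube = MarkedSurface(
        2, cube.shell.point_ids[np.abs(cube.shell.points[:, 0] - 20.0) < 0.7]
    )
    bp = bracket.shell.points
    mark_bracket = MarkedSurface(
        1, bracket.shell.point_ids[(np.abs(bp[:, 0] - 16.0) < 0.7) & (bp[:, 1] > 7.0)]
    )
    return lv, bracket, cube, mark_bracket, mark_cube


def marked_site_study(n_starts: int = 6, seed: int = 0) -> dict:
    """With one mating site painted, snap must choose that site from every start."""
    _, bracket, cube, mark_bracket, mark_cube = two_site_scene()
    rng = np.random.default_rng(seed)
    to_marked = 0
    finals = []
    for _ in range(n_starts):
        start = RigidTransform(
            translation=np.array([rng.uniform(-1.5, 0.8), *rng.uniform(-1.5, 1.5, 2)])
        )
        res = snap_to_fit(cube, mark_cube, bracket, mark_bracket, start, SnapParams())
        finals.append(res.final_pose)
        # left site closes the 4 mm gap (x -> -4); the right site is at x -> +4
        if abs(res.final_pose.translation[0] - (-4.0)) < 1.0:
            to_marked += 1
        cube.pose = RigidTransform.identity()
    # geometry edit outside the marked neighborhood must not change the result
    start = RigidTransform(translation=np.array([0.5, -0.4, 0.3]))
    res_a = snap_to_fit(cube, mark_cube, bracket, mark_bracket, start, SnapParams())
    cube.pose = RigidTransform.identity()
    far = cube.shell.points[:, 0] > 44.0
    cube.shell.points[far] += np.array([1.0, 0.0, 0.0])
    res_b = snap_to_fit(cube, mark_cube, bracket, mark_bracket, start, SnapParams())
    edit_shift = float(
        np.linalg.norm(res_b.final_pose.translation - res_a.final_pose.translation)
    )
    return {
        "n_starts": n_starts,
        "marked_site_rate_percent": 100.0 * to_marked / n_starts,
        "far_edit_pose_shift_mm": edit_shift,
    }


def grouping_stress(n_ops: int = 1000, seed: int = 0) -> dict:
    """Random attach/move/detach sequences; reports the worst pose deviation."""
    from .surface_model import DistanceField, Fragment, PointShell

    rng = np.random.default_rng(seed)
    frags = {}
    for label in range(1, 7):
        pts = rng.normal(scale=5.0, size=(10, 3))
        nrm = rng.normal(size=(10, 3))
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        frags[label] = Fragment(
            label=label,
            shell=PointShell(pts, nrm, np.arange(10)),
            field=DistanceField(np.full((3, 3, 3), 10.0), np.ones(3), np.array([500.0] * 3)),
            pose=RigidTransform.from_axis_angle(_unit(rng), rng.uniform(0, np.pi), rng.uniform(-5, 5, 3)),
        )
    scene = Scene(fragments=frags)
    gid = create_group(scene, [1, 2])
    members, free = {1, 2}, {3, 4, 5, 6}
    worst_t, worst_q = 0.0, 0.0

    def dev(p, q):
        nonlocal worst_t, worst_q
        worst_t = max(worst_t, float(np.linalg.norm(p.translation - q.translation)))
        worst_q = max(
            worst_q,
            float(min(np.linalg.norm(p.quaternion - q.quaternion),
                      np.linalg.norm(p.quaternion + q.quaternion))),
        )

    for _ in range(n_ops):
        op = rng.integers(3)
        if op == 0 and free:
            l = int(sorted(free)[rng.integers(len(free))])
            before = scene.fragments[l].pose
            attach(scene, gid, l)
            members.add(l)
            free.discard(l)
            g = scene.groups[gid]
            dev(compose(g.group_pose, g.member_offsets[l]), before)
        elif op == 1 and len(members) > 1:
            from .assembly import detach

            l = int(sorted(members)[rng.integers(len(members))])
            g = scene.groups[gid]
            expected = compose(g.group_pose, g.member_offsets[l])
            detach(scene, gid, l)
            members.discard(l)
            free.add(l)
            dev(scene.fragments[l].pose, expected)
        else:
            ms = sorted(members)
            rel = None
            if len(ms) >= 2:
                rel = compose(scene.fragments[ms[0]].pose.inverse(), scene.fragments[ms[1]].pose)
            g = scene.groups[gid]
            motion = RigidTransform.from_axis_angle(
                _unit(rng), rng.uniform(0, np.pi), rng.uniform(-5, 5, 3)
            )
            set_group_pose(scene, gid, compose(motion, g.group_pose))
            if rel is not None:
                now = compose(scene.fragments[ms[0]].pose.inverse(), scene.fragments[ms[1]].pose)
                dev(now, rel)
    return {"n_ops": n_ops, "max_translation_deviation_mm": worst_t, "max_quaternion_deviation": worst_q}


def end_to_end_closure(seed: int = 0, n_cuts: int = 2) -> dict:
    """Phantom → threshold → filter → label → group-assisted snap → report.

    The largest fragment anchors the reconstruction at its restoring pose;
    every other fragment starts (2 mm, 5°) off its truth pose, snaps onto an
    already-placed mating neighbor, and joins the placed group. The reduction
    report scores the final plan against the stored ground truth.
    """
    pt = generate_phantom(PhantomSpec(seed=seed, n_cuts=n_cuts, noise_components=3))
    v = intensity_volume(pt)
    lv = segment_fragments(v, threshold=350.0, min_size=100)

    # map segmentation labels onto phantom labels by majority overlap
    mapping = {}
    for l in lv.label_ids:
        overlap = pt.labeled.labels[lv.labels == l]
        mapping[int(l)] = int(np.bincount(overlap[overlap > 0]).argmax())
    frags = {mapping[int(l)]: f for l, f in build_fragments(lv).items()}
    for ph_label, f in frags.items():
        f.label = ph_label

    pairs = fracture_face_markings(pt, frags)
    adjacency: dict[int, list] = {l: [] for l in frags}
    for ma, mb in pairs:
        adjacency[ma.fragment_label].append((mb.fragment_label, mb, ma))
        adjacency[mb.fragment_label].append((ma.fragment_label, ma, mb))

    sizes = {l: len(f.shell) for l, f in frags.items()}
    anchor = max(sizes, key=sizes.get)
    frags[anchor].pose = pt.truth_poses[anchor]
    scene = Scene(fragments=frags)
    gid = create_group(scene, [anchor])

    placed = {anchor}
    rng = np.random.default_rng(seed + 5)
    n_snapped = 0
    remaining = [l for l in frags if l != anchor]
    while remaining:
        # next fragment: the one sharing the most marked points with placed ones
        def support(l):
            return sum(len(mo) for (nb, mo, mc) in adjacency[l] if nb in placed)

        remaining.sort(key=lambda l: (-support(l), l))
        nxt = remaining[0]
        if support(nxt) == 0:
            break  # no placed mating neighbor: cannot snap the rest
        remaining.pop(0)
        # adjacency tuples are (neighbor, neighbor's marking, own marking)
        nbrs = [(nb, m_nb, m_own) for (nb, m_nb, m_own) in adjacency[nxt] if nb in placed]
        moving_ids = np.concatenate([m_own.marked_ids for _, _, m_own in nbrs])
        m_moving = MarkedSurface(nxt, moving_ids)
        targets = [frags[nb] for nb, _, _ in nbrs]
        t_markings = [m_nb for _, m_nb, _ in nbrs]
        truth = pt.truth_poses[nxt]
        start = offset_pose(truth, frags[nxt].centroid, rng, 2.0, 5.0)
        res = snap_to_fit(frags[nxt], m_moving, targets, t_markings, start, SnapParams())
        frags[nxt].pose = res.final_pose
        attach(scene, gid, nxt)
        placed.add(nxt)
        n_snapped += 1
    # one refinement sweep: re-snap every placed fragment from its current
    # pose now that all of its mating neighbors are in place
    for l in sorted(placed - {anchor}):
        nbrs = [(nb, m_nb, m_own) for (nb, m_nb, m_own) in adjacency[l] if nb in placed]
        if not nbrs:
            continue
        m_moving = MarkedSurface(l, np.concatenate([m_own.marked_ids for _, _, m_own in nbrs]))
        from .assembly import detach

        detach(scene, gid, l)
        res = snap_to_fit(
            frags[l], m_moving, [frags[nb] for nb, _, _ in nbrs],
            [m_nb for _, m_nb, _ in nbrs], frags[l].pose, SnapParams(),
        )
        frags[l].pose = res.final_pose
        attach(scene, gid, l)
    # any fragment without a placed mating neighbor stays at truth (unscored snap)
    for l in frags:
        if l not in placed:
            frags[l].pose = pt.truth_poses[l]

    rep = reduction_report(scene, {l: pt.truth_poses[l] for l in frags})
    return {
        "n_fragments": len(frags),
        "n_snapped": n_snapped,
        "rms_translation_mm": rep.rms_translation,
        "rms_rotation_deg": rep.rms_rotation,
    }
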