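"""Snap-to-fit: attraction forces between painted fracture surfaces.

The user (here: a scripted cursor path) paints the fracture surface on both
fragments; only painted shell points enter the attraction model, which
prevents a fragment from snapping to false regions elsewhere on the surface.
From an approximate initial pose, each marked point of the moving fragment is
paired with its nearest marked point on the target fragment within a capture
radius, and pulled by a spring force scaled by the colinearity of the two
outward surface normals:

    w = max(0, -n_moving · n_target) ** p

Mating fracture faces have opposing outward normals, so w is 1 for a perfect
mate and 0 for same-direction or perpendicular normals; fragments with
matching surfaces therefore attract more strongly than damaged ones. Damped
descent on the attraction wrench (plus, optionally, the contact wrench) snaps
the fragment into the closest *local* stable fit. The mean weight over the
active pairs is reported as a similarity score in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .contact_dynamics import CouplingParams, contact_wrench
from .core_geometry import RigidTransform, Wrench
from .surface_model import Fragment


@dataclass
class MarkedSurface:
    """The painted subset of a fragment's shell points."""

    fragment_label: int
    marked_ids: np.ndarray

    def __post_init__(self):
        self.marked_ids = np.unique(np.asarray(self.marked_ids, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.marked_ids)

    def validate(self, frag: Fragment) -> None:
        if len(self.marked_ids) and not np.isin(self.marked_ids, frag.shell.point_ids).all():
            raise ValueError("marked_ids contains ids not on the fragment's shell")


@dataclass(frozen=True)
class SnapParams:
    """Attraction-force constants.

    k_a : attraction stiffness per pair, N/mm
    capture_radius : max pairing distance, mm
    colinearity_exponent : sharpens selectivity of the normal-colinearity weight
    contact_enabled : include the penalty contact wrench during descent
    contact_stiffness : penalty stiffness (N/mm per point) used *during snap*;
        softer than the manipulation default, since a stiff penalty biases the
        snapped equilibrium outward by a sub-voxel standoff while a soft one
        merely regularizes interpenetration as attraction finds the fit
    """

    k_a: float = 1.0
    capture_radius: float = 5.0
    colinearity_exponent: float = 2.0
    max_iters: int = 400
    tol: float = 1e-4
    contact_enabled: bool = True
    contact_stiffness: float = 5.0

    def __post_init__(self):
        if self.capture_radius <= 0 or self.k_a <= 0:
            raise ValueError("capture_radius and k_a must be positive")
        if self.colinearity_exponent < 1:
            raise ValueError("colinearity_exponent must be >= 1")


@dataclass
class SnapResult:
    final_pose: RigidTransform
    converged: bool
    similarity: float
    iterations: int
    residual_rms: float
    n_pairs: int = 0


def paint_surface(
    frag: Fragment,
    cursor_path,
    brush_radius: float,
    existing: MarkedSurface | None = None,
) -> MarkedSurface:
    """Mark every shell point within ``brush_radius`` of any cursor path point.

    Painting is cumulative (pass ``existing`` to extend a marking) and
    idempotent. Cursor path points are world coordinates (mm).
    """
    path = np.atleast_2d(np.asarray(cursor_path, dtype=float))
    if path.size == 0:
        raise ValueError("cursor path must be non-empty")
    tree = cKDTree(frag.world_shell_points())
    hits: set[int] = set()
    for lists in tree.query_ball_point(path, r=brush_radius):
        hits.update(lists)
    ids = frag.shell.point_ids[np.asarray(sorted(hits), dtype=int)] if hits else np.empty(0, np.int64)
    if existing is not None:
        if existing.fragment_label != frag.label:
            raise ValueError("existing marking belongs to a different fragment")
        ids = np.union1d(existing.marked_ids, ids)
    return MarkedSurface(fragment_label=frag.label, marked_ids=ids)


def colinearity_weight(n_moving, n_target, p: float = 2.0):
    """Similarity of two unit surface normals as mating candidates, in [0, 1].

    Outward normals of mating fracture faces oppose each other, so the weight
    is the clamped negative dot product raised to ``p``.
    """
    dot = np.sum(np.asarray(n_moving, float) * np.asarray(n_target, float), axis=-1)
    return np.maximum(0.0, -dot) ** p


def _marked_world(frag: Fragment, marking: MarkedSurface):
    idx = np.searchsorted(frag.shell.point_ids, marking.marked_ids)
    pts = frag.pose.apply(frag.shell.points[idx])
    nrm = frag.pose.rotate_vectors(frag.shell.normals[idx])
    return pts, nrm


def attraction_wrench(
    moving: Fragment,
    moving_marking: MarkedSurface,
    target: Fragment,
    target_marking: MarkedSurface,
    sp: SnapParams,
) -> tuple[Wrench, float, int]:
    """Attraction wrench about the moving centroid, plus similarity and pair count.

    Each marked moving point pairs with the nearest marked target point within
    the capture radius; per pair the force is ``k_a * w * (target - moving)``
    with ``w`` the colinearity weight of the pair's world normals. Unmarked
    points and pairs beyond the capture radius contribute nothing. The
    similarity is the mean weight over active pairs (0 if none).
    """
    centroid_w = moving.world_centroid
    if len(moving_marking) == 0 or len(target_marking) == 0:
        import logging

        logging.getLogger(__name__).warning("empty marking: attraction wrench is zero")
        return Wrench.zero(centroid_w), 0.0, 0
    mp, mn = _marked_world(moving, moving_marking)
    tp, tn = _marked_world(target, target_marking)
    # target points sorted by point id -> deterministic nearest-neighbor ties
    tree = cKDTree(tp)
    dist, j = tree.query(mp, distance_upper_bound=sp.capture_radius)
    ok = np.isfinite(dist)
    if not ok.any():
        return Wrench.zero(centroid_w), 0.0, 0
    mp, mn = mp[ok], mn[ok]
    j = j[ok]
    w = colinearity_weight(mn, tn[j], sp.colinearity_exponent)
    dvec = tp[j] - mp
    f = sp.k_a * w[:, None] * dvec
    force = f.sum(axis=0)
    torque = np.cross(mp - centroid_w, f).sum(axis=0)
    similarity = float(w.mean())
    return Wrench(force, torque, centroid_w), similarity, int(ok.sum())


def snap_to_fit(
    moving: Fragment,
    moving_marking: MarkedSurface,
    target: Fragment | list[Fragment],
    target_marking: MarkedSurface | list[MarkedSurface],
    start: RigidTransform,
    sp: SnapParams,
    cp: CouplingParams | None = None,
) -> SnapResult:
    """Damped descent on attraction (+ optional contact) to the closest stable fit.

    ``target`` may be a list of fragments (e.g. the already-placed members of
    a reconstruction) with one marking each; their marked points are pooled
    into a single attraction field. The result is a local equilibrium: small
    perturbations of the final pose return to it. Never raises on
    non-convergence; the flag and diagnostics are returned instead.
    """
    from .contact_dynamics import _rotate_about

    cp = cp or CouplingParams()
    targets = list(target) if isinstance(target, (list, tuple)) else [target]
    markings = (
        list(target_marking)
        if isinstance(target_marking, (list, tuple))
        else [target_marking]
    )
    if len(targets) != len(markings):
        raise ValueError("need one marking per target fragment")
    moving.pose = start
    pose = start
    converged = False
    similarity = 0.0
    n_pairs = 0
    resid = np.inf
    it = 0
    # moment-arm scale for converting torque to a rotation step
    r2 = float(np.mean(np.sum((moving.shell.points - moving.centroid) ** 2, axis=1)))
    r2 = max(r2, 1e-6)
    for it in range(1, sp.max_iters + 1):
        aws = [
            attraction_wrench(moving, moving_marking, tg, mk, sp)
            for tg, mk in zip(targets, markings)
        ]
        total_f = np.sum([w.force for w, _, _ in aws], axis=0)
        total_tau = np.sum([w.torque for w, _, _ in aws], axis=0)
        n_pairs = int(sum(n for _, _, n in aws))
        similarity = (
            float(sum(s * n for _, s, n in aws) / n_pairs) if n_pairs else 0.0
        )
        if sp.contact_enabled:
            cres = contact_wrench(moving, targets, k_c=sp.contact_stiffness)
            total_f += cres.wrench.force
            total_tau += cres.wrench.torque
        if n_pairs == 0:
            break
        scale = sp.k_a * n_pairs
        step_t = 0.5 * total_f / scale
        step_r = 0.5 * total_tau / (scale * r2)
        if np.linalg.norm(step_t) <= sp.tol and np.linalg.norm(step_r) * np.sqrt(r2) <= sp.tol:
            converged = True
            break
        # cap steps for stability far from equilibrium
        nt = np.linalg.norm(step_t)
        if nt > 1.0:
            step_t *= 1.0 / nt
        nr = np.linalg.norm(step_r)
        if nr > 0.1:
            step_r *= 0.1 / nr
        centroid_w = pose.apply(moving.centroid)
        pose = _rotate_about(
            RigidTransform(pose.quaternion, pose.translation + step_t),
            step_r,
            centroid_w + step_t,
        )
        moving.pose = pose
    # residual rms over the final pairing (pooled across targets)
    mp, _ = _marked_world(moving, moving_marking) if len(moving_marking) else (np.empty((0, 3)), None)
    pooled = [
        _marked_world(tg, mk)[0] for tg, mk in zip(targets, markings) if len(mk)
    ]
    if n_pairs > 0 and pooled:
        tp = np.vstack(pooled)
        dist, _ = cKDTree(tp).query(mp, distance_upper_bound=sp.capture_radius)
        dist = dist[np.isfinite(dist)]
        resid = float(np.sqrt(np.mean(dist**2))) if dist.size else np.inf
    else:
        resid = np.inf
    return SnapResult(
        final_pose=pose,
        converged=converged,
        similarity=similarity,
        iterations=it,
        residual_rms=float(resid),
        n_pairs=n_pairs,
    )
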