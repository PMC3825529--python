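"""Six-DOF contact and static virtual coupling, stepped quasi-statically.

The manipulated fragment is tied to a (simulated) handle by a translational
and a rotational spring — the *virtual coupling* — while penalty contact
forces from every static fragment's signed distance field push it out of
penetration. The fragment pose is the quasi-static equilibrium of the two
wrenches, tracked by damped first-order descent along a scripted handle
trajectory. This reproduces, deterministically and offline, the user-visible
behavior of the haptic loop: the fragment follows the handle in free space
and stops at other fragments' surfaces instead of penetrating them.

Penetration is bounded: at equilibrium a spring stretch of ``D`` mm against a
single contact yields penetration ``k_t * D / k_c``; with the default
stiffness ratio ``k_c / k_t = 50`` per contact point, pressing 5 mm into a
wall leaves at most 0.1 mm of penetration plus one interpolation voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core_geometry import (
    RigidTransform,
    Wrench,
    relative_rotation_vector,
)
from .surface_model import Fragment


@dataclass(frozen=True)
class CouplingParams:
    """Spring and solver constants for the virtual coupling.

    k_t : translational stiffness, N/mm
    k_r : rotational stiffness, N·mm/rad
    k_c : contact penalty stiffness per shell point, N/mm
    step_scale : damped-descent step (fraction of the equilibrium step)
    max_iters : iteration cap per quasi-static step
    tol : residual tolerance, expressed as equivalent displacement in mm
          (converged when |force|/k_t and |torque|/k_r are both below it)
    """

    k_t: float = 1.0
    k_r: float = 100.0
    k_c: float = 50.0
    step_scale: float = 0.4
    max_iters: int = 300
    tol: float = 1e-4

    def __post_init__(self):
        if min(self.k_t, self.k_r, self.k_c) <= 0:
            raise ValueError("all stiffnesses must be strictly positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class Contact:
    point_id: int
    static_label: int
    penetration: float
    normal: np.ndarray  # world frame, unit


@dataclass
class ContactResult:
    wrench: Wrench              # about the moving fragment's world centroid
    max_penetration: float
    contacts: list[Contact]


@dataclass
class HandleTrajectory:
    """Timed handle poses; times strictly increasing."""

    samples: list[tuple[float, RigidTransform]]

    def __post_init__(self):
        times = [t for t, _ in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("trajectory times must be strictly increasing")

    def to_json(self) -> str:
        return json.dumps(
            {"samples": [
                {"t": t, "q": p.quaternion.tolist(), "p": p.translation.tolist()}
                for t, p in self.samples
            ]}
        )

    @staticmethod
    def from_json(text: str) -> "HandleTrajectory":
        d = json.loads(text)
        return HandleTrajectory(
            [(float(s["t"]), RigidTransform(np.asarray(s["q"], float), np.asarray(s["p"], float)))
             for s in d["samples"]]
        )


def contact_wrench(
    moving: Fragment,
    statics: list[Fragment],
    k_c: float = 50.0,
    use_pruning: bool = True,
) -> ContactResult:
    """Penalty contact wrench on ``moving`` from all static fragments.

    Every moving shell point whose world position falls inside a static
    fragment (negative signed distance in that fragment's field) contributes a
    force ``k_c * depth`` along the static field's outward gradient. Forces
    and torques are summed about the moving fragment's world centroid.

    ``use_pruning`` culls shell points outside a static field's grid via a
    bounding-box check before sampling; the grid itself returns "outside" for
    such points, so pruning can never change the result.
    """
    centroid_w = moving.world_centroid
    pts_w = moving.world_shell_points()
    force = np.zeros(3)
    torque = np.zeros(3)
    contacts: list[Contact] = []
    max_pen = 0.0
    for st in statics:
        if st is moving:
            raise ValueError("moving fragment cannot be in the static list")
        pts_s = st.pose.inverse().apply(pts_w)
        cand = np.arange(len(pts_s))
        if use_pruning:
            lo, hi = st.field.bounds()
            inside_box = np.all((pts_s >= lo) & (pts_s <= hi), axis=1)
            cand = cand[inside_box]
            if cand.size == 0:
                continue
        d = st.field.sample(pts_s[cand])
        pen_mask = d < 0
        if not pen_mask.any():
            continue
        sel = cand[pen_mask]
        depth = -d[pen_mask]
        g = st.field.gradient(pts_s[sel])
        gn = np.linalg.norm(g, axis=1, keepdims=True)
        gn = np.where(gn < 1e-9, 1.0, gn)
        n_local = g / gn
        n_world = st.pose.rotate_vectors(n_local)
        f = k_c * depth[:, None] * n_world
        force += f.sum(axis=0)
        torque += np.cross(pts_w[sel] - centroid_w, f).sum(axis=0)
        max_pen = max(max_pen, float(depth.max()))
        order = np.argsort(moving.shell.point_ids[sel])
        for i in order:
            contacts.append(
                Contact(
                    point_id=int(moving.shell.point_ids[sel[i]]),
                    static_label=st.label,
                    penetration=float(depth[i]),
                    normal=n_world[i],
                )
            )
    return ContactResult(
        wrench=Wrench(force, torque, centroid_w),
        max_penetration=max_pen,
        contacts=contacts,
    )


def coupling_wrench(
    handle: RigidTransform, fragment_pose: RigidTransform, p: CouplingParams,
    centroid_world=None,
) -> Wrench:
    """Virtual-coupling spring wrench pulling the fragment toward the handle.

    Force ``k_t * (handle.t - fragment.t)``; torque ``k_r`` times the
    shortest-arc axis-angle of the relative rotation fragment→handle, about
    the fragment's world centroid (``centroid_world``; defaults to the
    fragment pose translation).
    """
    f = p.k_t * (handle.translation - fragment_pose.translation)
    tau = p.k_r * relative_rotation_vector(fragment_pose, handle)
    ref = fragment_pose.translation if centroid_world is None else np.asarray(centroid_world, float)
    return Wrench(f, tau, ref)


def _rotate_about(pose: RigidTransform, rotvec: np.ndarray, pivot_world: np.ndarray) -> RigidTransform:
    """Rotate a pose by ``rotvec`` (axis-angle, rad) about a world pivot point."""
    from scipy.spatial.transform import Rotation

    dR = Rotation.from_rotvec(rotvec)
    new_rot = dR * pose.rotation
    new_t = pivot_world + dR.apply(pose.translation - pivot_world)
    return RigidTransform.from_rotation(new_rot, new_t)


@dataclass
class StepResult:
    pose: RigidTransform
    contact: ContactResult
    converged: bool
    iterations: int


def step_quasistatic(
    handle: RigidTransform,
    moving: Fragment,
    statics: list[Fragment],
    p: CouplingParams,
) -> StepResult:
    """Damped descent to the equilibrium of coupling + contact wrenches.

    In free space the fixed point is the handle pose; against an obstruction
    the spring stretch balances the contact penalty, bounding penetration by
    ``(k_t / k_c) * |stretch|`` for a single contact (less for several).
    Never raises on non-convergence: returns the best pose with a flag.
    """
    pose = moving.pose
    contact = contact_wrench(moving, statics, k_c=p.k_c)
    converged = False
    it = 0
    # mean squared moment arm, for torque -> rotation-step scaling
    r2 = float(np.mean(np.sum((moving.shell.points - moving.centroid) ** 2, axis=1)))
    r2 = max(r2, 1e-6)
    cap_t = float(np.linalg.norm(moving.field.spacing))  # one voxel diagonal per iter
    for it in range(1, p.max_iters + 1):
        centroid_w = pose.apply(moving.centroid)
        cw = coupling_wrench(handle, pose, p, centroid_world=centroid_w)
        total_f = cw.force + contact.wrench.force
        total_tau = cw.torque + contact.wrench.torque
        if (
            np.linalg.norm(total_f) <= p.tol * p.k_t
            and np.linalg.norm(total_tau) <= p.tol * p.k_r
        ):
            converged = True
            break
        # preconditioned descent: the effective stiffness includes the active
        # contacts along their mean normal, so one full step in free space
        # jumps to the handle, stiff contact states stay stable, and frictionless
        # tangential tracking is not over-damped
        n_c = len(contact.contacts)
        if n_c:
            u = np.sum([c.normal for c in contact.contacts], axis=0)
            un = np.linalg.norm(u)
            u = u / un if un > 1e-9 else np.zeros(3)
            f_n = (total_f @ u) * u
            f_t = total_f - f_n
            dt = p.step_scale * (f_n / (p.k_t + p.k_c * n_c) + f_t / p.k_t)
        else:
            dt = p.step_scale * total_f / p.k_t
        drot = p.step_scale * total_tau / (p.k_r + p.k_c * n_c * r2)
        nt = np.linalg.norm(dt)
        if nt > cap_t:
            dt *= cap_t / nt
        nr = np.linalg.norm(drot)
        if nr > 0.1:
            drot *= 0.1 / nr
        pose = _rotate_about(
            RigidTransform(pose.quaternion, pose.translation + dt), drot,
            centroid_w + dt,
        )
        moving.pose = pose
        contact = contact_wrench(moving, statics, k_c=p.k_c)
    moving.pose = pose
    return StepResult(pose=pose, contact=contact, converged=converged, iterations=it)


@dataclass
class SimulationLog:
    steps: list[dict] = field(default_factory=list)

    @property
    def max_penetration(self) -> float:
        return max((s["max_penetration"] for s in self.steps), default=0.0)

    def to_csv(self, path: str) -> None:
        import csv

        cols = ["step", "time", "q", "t", "force_norm", "torque_norm",
                "max_penetration", "n_contacts", "converged"]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for s in self.steps:
                w.writerow([s[c] for c in cols])


def simulate_manipulation(
    traj: HandleTrajectory,
    moving: Fragment,
    statics: list[Fragment],
    p: CouplingParams,
) -> tuple[list[RigidTransform], SimulationLog]:
    """Step the moving fragment along a handle trajectory; deterministic.

    Returns the pose after each trajectory sample plus a per-step log
    (wrench norms, max penetration, contact count, convergence flag).
    """
    poses: list[RigidTransform] = []
    log = SimulationLog()
    for i, (t, handle) in enumerate(traj.samples):
        res = step_quasistatic(handle, moving, statics, p)
        poses.append(res.pose)
        cw = coupling_wrench(handle, res.pose, p, centroid_world=res.pose.apply(moving.centroid))
        tot_f = cw.force + res.contact.wrench.force
        tot_tau = cw.torque + res.contact.wrench.torque
        log.steps.append(
            {
                "step": i,
                "time": t,
                "q": res.pose.quaternion.tolist(),
                "t": res.pose.translation.tolist(),
                "force_norm": float(np.linalg.norm(res.contact.wrench.force)),
                "torque_norm": float(np.linalg.norm(res.contact.wrench.torque)),
                "residual_force": float(np.linalg.norm(tot_f)),
                "residual_torque": float(np.linalg.norm(tot_tau)),
                "max_penetration": res.contact.max_penetration,
                "n_contacts": len(res.contact.contacts),
                "converged": res.converged,
            }
        )
    return poses, log
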