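"""Rigid transforms and wrenches shared by every other module.

Conventions
-----------
* Quaternions are scalar-first ``[w, x, y, z]``, unit norm, active rotations,
  right-handed. ``q`` and ``-q`` denote the same rotation and compare equal.
* All world coordinates are millimeters. Voxel index ``i`` on an axis with
  spacing ``s`` and origin ``o`` maps to world coordinate ``o + (i + 0.5) * s``
  (voxel-center convention).
* A :class:`Wrench` is a force (N) plus a torque (N·mm) about a stated world
  reference point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


def _as_finite(a, shape, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class RigidTransform:
    """A rotation (unit quaternion, scalar-first) followed by a translation (mm).

    Maps fragment-local points ``p`` to world points ``R p + t``.
    """

    quaternion: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        q = _as_finite(self.quaternion, (4,), "quaternion")
        t = _as_finite(self.translation, (3,), "translation")
        n = np.linalg.norm(q)
        if n < 1e-12:
            raise ValueError("quaternion has zero norm")
        object.__setattr__(self, "quaternion", q / n)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def from_rotation(rot: Rotation, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        x, y, z, w = rot.as_quat()
        return RigidTransform(np.array([w, x, y, z]), np.asarray(translation, float))

    @staticmethod
    def from_axis_angle(axis, angle_rad: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        return RigidTransform.from_rotation(Rotation.from_rotvec(axis * angle_rad), translation)

    @staticmethod
    def from_matrix(m) -> "RigidTransform":
        m = _as_finite(m, (4, 4), "matrix")
        return RigidTransform.from_rotation(Rotation.from_matrix(m[:3, :3]), m[:3, 3])

    # -- views -------------------------------------------------------------
    @property
    def rotation(self) -> Rotation:
        w, x, y, z = self.quaternion
        return Rotation.from_quat([x, y, z, w])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation.as_matrix()
        m[:3, 3] = self.translation
        return m

    # -- algebra -----------------------------------------------------------
    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.inv()
        return RigidTransform.from_rotation(rinv, -rinv.apply(self.translation))

    def apply(self, points) -> np.ndarray:
        """Transform one point or an ``(N, 3)`` point set (mm)."""
        pts = np.asarray(points, dtype=float)
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite values")
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = self.rotation.apply(pts) + self.translation
        return out[0] if single else out

    def rotate_vectors(self, vectors) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return self.rotation.apply(np.asarray(vectors, dtype=float))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"q": self.quaternion.tolist(), "t": self.translation.tolist()}

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform":
        return RigidTransform(np.asarray(d["q"], float), np.asarray(d["t"], float))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        q = np.round(self.quaternion, 6)
        t = np.round(self.translation, 6)
        return f"RigidTransform(q={q.tolist()}, t={t.tolist()})"


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition ``a ∘ b``: the result maps ``p`` to ``a(b(p))``."""
    rot = a.rotation * b.rotation
    return RigidTransform.from_rotation(rot, a.rotation.apply(b.translation) + a.translation)


def rotation_angle_between(a: RigidTransform, b: RigidTransform) -> float:
    """Shortest-arc angle (rad) between the rotations of two transforms."""
    return float((a.rotation.inv() * b.rotation).magnitude())


def relative_rotation_vector(from_pose: RigidTransform, to_pose: RigidTransform) -> np.ndarray:
    """Shortest-arc axis-angle vector (rad) taking ``from_pose`` rotation to ``to_pose``."""
    return (to_pose.rotation * from_pose.rotation.inv()).as_rotvec()


def transforms_close(
    a: RigidTransform,
    b: RigidTransform,
    atol_t: float = 1e-9,
    atol_q: float = 1e-9,
) -> bool:
    """Equality up to the q/-q sign ambiguity."""
    dq = min(
        np.linalg.norm(a.quaternion - b.quaternion),
        np.linalg.norm(a.quaternion + b.quaternion),
    )
    return dq <= atol_q and np.linalg.norm(a.translation - b.translation) <= atol_t


@dataclass(frozen=True)
class Wrench:
    """Force (N) and torque (N·mm) about ``reference_point`` (mm, world frame)."""

    force: np.ndarray
    torque: np.ndarray
    reference_point: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "force", _as_finite(self.force, (3,), "force"))
        object.__setattr__(self, "torque", _as_finite(self.torque, (3,), "torque"))
        object.__setattr__(
            self, "reference_point", _as_finite(self.reference_point, (3,), "reference_point")
        )

    @staticmethod
    def zero(reference_point=(0.0, 0.0, 0.0)) -> "Wrench":
        return Wrench(np.zeros(3), np.zeros(3), np.asarray(reference_point, float))

    def __add__(self, other: "Wrench") -> "Wrench":
        if not np.allclose(self.reference_point, other.reference_point):
            other = shift_wrench(other, self.reference_point)
        return Wrench(self.force + other.force, self.torque + other.torque, self.reference_point)


def shift_wrench(w: Wrench, new_point) -> Wrench:
    """Re-express a wrench about a new reference point.

    The force is unchanged; the torque gains ``(old_point - new_point) × force``.
    """
    new_point = _as_finite(new_point, (3,), "new_point")
    torque = w.torque + np.cross(w.reference_point - new_point, w.force)
    return Wrench(w.force.copy(), torque, new_point)
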