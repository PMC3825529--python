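"""Scene state for the planning workflow: grouping, plan export, error reporting.

Fragments positioned relative to one another can be grouped and manipulated
as one rigid unit; further fragments may be attached and later detached.
Attaching is motion-free: the member's local→group offset is computed so its
world pose does not change, and detaching leaves the fragment at its current
world pose. A group behaves as a single rigid body — the union of member
shells, contact-queried against each member's field (intra-group contacts are
skipped).

The plan — fragment poses, groups, surface markings — serializes to a
versioned JSON file; a reduction report compares planned poses against
ground-truth restoring transforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core_geometry import RigidTransform, compose, rotation_angle_between
from .snap_to_fit import MarkedSurface
from .surface_model import Fragment

PLAN_FORMAT_VERSION = 1


@dataclass
class Group:
    group_id: int
    member_labels: list[int]
    group_pose: RigidTransform
    member_offsets: dict[int, RigidTransform]  # member local -> group frame


@dataclass
class Scene:
    fragments: dict[int, Fragment]
    groups: dict[int, Group] = field(default_factory=dict)
    markings: dict[int, MarkedSurface] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    _next_group_id: int = 1

    def group_of(self, label: int) -> int | None:
        for gid, g in self.groups.items():
            if label in g.member_labels:
                return gid
        return None

    def world_pose(self, label: int) -> RigidTransform:
        return self.fragments[label].pose


def create_group(scene: Scene, labels) -> int:
    """Group fragments into one rigid unit; world poses are unchanged."""
    labels = [int(l) for l in labels]
    for l in labels:
        if l not in scene.fragments:
            raise KeyError(f"fragment {l} not in scene")
        gid = scene.group_of(l)
        if gid is not None:
            raise ValueError(f"fragment {l} already belongs to group {gid}")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in group request")
    group_id = scene._next_group_id
    scene._next_group_id += 1
    group_pose = scene.fragments[labels[0]].pose
    offsets = {
        l: compose(group_pose.inverse(), scene.fragments[l].pose) for l in labels
    }
    scene.groups[group_id] = Group(group_id, list(labels), group_pose, offsets)
    return group_id


def attach(scene: Scene, group_id: int, label: int) -> None:
    """Add a fragment to a group without moving it."""
    g = scene.groups[group_id]
    other = scene.group_of(label)
    if other is not None:
        raise ValueError(f"fragment {label} already belongs to group {other}, cannot attach to {group_id}")
    if label not in scene.fragments:
        raise KeyError(f"fragment {label} not in scene")
    g.member_offsets[label] = compose(g.group_pose.inverse(), scene.fragments[label].pose)
    g.member_labels.append(label)


def detach(scene: Scene, group_id: int, label: int) -> None:
    """Remove a member; it keeps its current world pose."""
    g = scene.groups[group_id]
    if label not in g.member_labels:
        raise ValueError(f"fragment {label} is not a member of group {group_id}")
    scene.fragments[label].pose = compose(g.group_pose, g.member_offsets[label])
    g.member_labels.remove(label)
    del g.member_offsets[label]
    if not g.member_labels:
        del scene.groups[group_id]


def set_group_pose(scene: Scene, group_id: int, pose: RigidTransform) -> None:
    """Move the whole group rigidly; relative member poses are preserved exactly."""
    g = scene.groups[group_id]
    g.group_pose = pose
    for l in g.member_labels:
        scene.fragments[l].pose = compose(pose, g.member_offsets[l])


def group_as_rigid_body(scene: Scene, group_id: int) -> Fragment:
    """The group as one rigid body: union shell in the group frame.

    Shell point ids are offset per member (``label * 10**7 + id``) to stay
    unique; the returned fragment's field is the first member's (contact
    queries on groups should iterate member fields instead).
    """
    g = scene.groups[group_id]
    pts, nrms, ids = [], [], []
    inv = g.group_pose.inverse()
    for l in g.member_labels:
        fr = scene.fragments[l]
        off = g.member_offsets[l]
        pts.append(off.apply(fr.shell.points))
        nrms.append(off.rotate_vectors(fr.shell.normals))
        ids.append(fr.shell.point_ids + int(l) * 10_000_000)
    from .surface_model import PointShell

    shell = PointShell(np.vstack(pts), np.vstack(nrms), np.concatenate(ids))
    first = scene.fragments[g.member_labels[0]]
    frag = Fragment(label=-group_id, shell=shell, field=first.field, pose=g.group_pose)
    return frag


# ---------------------------------------------------------------------------
# Plan serialization
# ---------------------------------------------------------------------------

def export_plan(scene: Scene, path: str) -> None:
    doc = {
        "format_version": PLAN_FORMAT_VERSION,
        "provenance": scene.provenance,
        "fragments": {
            str(l): f.pose.to_dict() for l, f in sorted(scene.fragments.items())
        },
        "groups": {
            str(gid): {
                "members": g.member_labels,
                "pose": g.group_pose.to_dict(),
                "offsets": {str(l): t.to_dict() for l, t in g.member_offsets.items()},
            }
            for gid, g in sorted(scene.groups.items())
        },
        "markings": {
            str(l): {"fragment": m.fragment_label, "marked_ids": m.marked_ids.tolist()}
            for l, m in sorted(scene.markings.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def import_plan(path: str, fragments: dict[int, Fragment]) -> Scene:
    """Rebuild a scene's poses/groups/markings onto prebuilt fragments."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"plan file {path} is not valid JSON: line {e.lineno}: {e.msg}") from e
    ver = doc.get("format_version")
    if ver != PLAN_FORMAT_VERSION:
        raise ValueError(f"plan format version {ver!r} not supported (expected {PLAN_FORMAT_VERSION})")
    scene = Scene(fragments=fragments, provenance=doc.get("provenance", {}))
    for l_str, pd in doc["fragments"].items():
        l = int(l_str)
        if l not in fragments:
            raise KeyError(f"plan references fragment {l} not provided")
        fragments[l].pose = RigidTransform.from_dict(pd)
    max_gid = 0
    for gid_str, gd in doc.get("groups", {}).items():
        gid = int(gid_str)
        max_gid = max(max_gid, gid)
        scene.groups[gid] = Group(
            group_id=gid,
            member_labels=[int(m) for m in gd["members"]],
            group_pose=RigidTransform.from_dict(gd["pose"]),
            member_offsets={int(l): RigidTransform.from_dict(t) for l, t in gd["offsets"].items()},
        )
    scene._next_group_id = max_gid + 1
    for l_str, md in doc.get("markings", {}).items():
        scene.markings[int(l_str)] = MarkedSurface(
            fragment_label=int(md["fragment"]),
            marked_ids=np.asarray(md["marked_ids"], dtype=np.int64),
        )
    return scene


# ---------------------------------------------------------------------------
# Reduction quality
# ---------------------------------------------------------------------------

@dataclass
class ReductionReport:
    per_fragment: dict[int, tuple[float, float]]  # label -> (trans err mm, rot err deg)
    rms_translation: float
    rms_rotation: float


def reduction_report(scene: Scene, truth: dict[int, RigidTransform]) -> ReductionReport:
    """Per-fragment pose error against ground truth, plus aggregate RMS.

    Rotation error is the shortest-arc angle between the two rotations (deg);
    translation error is the distance between the two poses' images of the
    fragment centroid (mm), so it is invariant to the local-frame origin.
    """
    missing = [l for l in scene.fragments if l not in truth]
    if missing:
        raise KeyError(f"truth is missing labels {missing}")
    per: dict[int, tuple[float, float]] = {}
    for l, fr in sorted(scene.fragments.items()):
        tp = truth[l]
        t_err = float(np.linalg.norm(fr.pose.apply(fr.centroid) - tp.apply(fr.centroid)))
        r_err = float(np.degrees(rotation_angle_between(fr.pose, tp)))
        per[l] = (t_err, r_err)
    te = np.array([v[0] for v in per.values()])
    re = np.array([v[1] for v in per.values()])
    return ReductionReport(
        per_fragment=per,
        rms_translation=float(np.sqrt(np.mean(te**2))),
        rms_rotation=float(np.sqrt(np.mean(re**2))),
    )
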