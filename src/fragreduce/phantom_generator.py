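"""Synthetic fractured-bone phantoms with ground truth.

A phantom starts from an intact base shape (cube, ellipsoid shell, or a
mandible-like bent tube), is cut into fragments by randomized rough surfaces,
and each fragment is displaced by a known rigid transform. The stored truth
poses restore every displaced fragment to the intact configuration, so
segmentation, contact, snap-to-fit and the reduction report can all be scored
against exact ground truth.

Cut surfaces are planes perturbed by smooth low-frequency sinusoidal noise
(amplitude ``cut_roughness`` mm), which interdigitates the mating faces so a
snapped fit has a unique local minimum — flat cuts would leave in-plane
translation unobservable. Optional face erosion emulates compression-fracture
damage (missing surface), and sub-100-voxel noise specks give the
small-component filter something to remove. All randomness derives from the
single spec seed: attempt ``a`` uses ``default_rng([seed, a])``, and
per-fragment displacement draws use ``default_rng([seed, attempt, label])``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .contact_dynamics import HandleTrajectory
from .core_geometry import RigidTransform, compose
from .snap_to_fit import MarkedSurface
from .surface_model import Fragment
from .volume_segmentation import IntensityVolume, LabeledVolume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; identical specs yield identical phantoms."""

    base_shape: str = "cube"  # cube | ellipsoid_shell | bent_tube
    volume_shape: tuple[int, int, int] = (80, 80, 80)
    spacing: tuple[float, float, float] = (0.35, 0.35, 0.60)
    n_cuts: int = 1
    cut_roughness: float = 1.5          # mm, amplitude of surface perturbation
    displacement_mm: tuple[float, float] = (1.5, 4.0)
    displacement_deg: tuple[float, float] = (3.0, 12.0)
    erosion_voxels: int = 0             # compression-fracture face damage
    noise_components: int = 0           # junk specks for the filter to remove
    noise_size_range: tuple[int, int] = (5, 60)   # voxels, always < 100
    seed: int = 0

    def __post_init__(self):
        if self.base_shape not in ("cube", "ellipsoid_shell", "bent_tube"):
            raise ValueError(f"unknown base_shape {self.base_shape!r}")
        if self.noise_size_range[1] >= 100:
            raise ValueError("noise specks must stay below 100 voxels")


@dataclass
class CutSurface:
    """A rough cut: signed field g(x) = (x - point)·normal + Σ a_k sin(k·x + φ_k)."""

    point: np.ndarray
    normal: np.ndarray
    amplitudes: np.ndarray
    wavevectors: np.ndarray  # (K, 3), rad/mm
    phases: np.ndarray

    def evaluate(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        g = (pts - self.point) @ self.normal
        if len(self.amplitudes):
            g = g + np.sin(pts @ self.wavevectors.T + self.phases) @ self.amplitudes
        return g


@dataclass
class PhantomTruth:
    """Generated phantom: displaced labels, intact labels, restoring transforms."""

    spec: PhantomSpec
    labeled: LabeledVolume                      # displaced state
    intact: LabeledVolume
    truth_poses: dict[int, RigidTransform]      # displaced -> intact
    displacements: dict[int, RigidTransform]    # intact -> displaced
    cuts: list[CutSurface]
    noise_mask: np.ndarray | None = None


def _voxel_centers(shape, spacing) -> np.ndarray:
    """(nx, ny, nz, 3) world coordinates of voxel centers (origin at 0)."""
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    return (idx + 0.5) * np.asarray(spacing)


def _base_mask(spec: PhantomSpec, coords: np.ndarray) -> np.ndarray:
    extent = np.asarray(spec.volume_shape) * np.asarray(spec.spacing)
    c = extent / 2
    x = coords - c
    if spec.base_shape == "cube":
        half = 0.32 * extent
        return np.all(np.abs(x) <= half, axis=-1)
    if spec.base_shape == "ellipsoid_shell":
        r_out = 0.42 * extent
        r_in = 0.27 * extent
        q_out = np.sum((x / r_out) ** 2, axis=-1)
        q_in = np.sum((x / r_in) ** 2, axis=-1)
        return (q_out <= 1.0) & (q_in >= 1.0)
    # bent_tube: arch of a circle in the xy-plane with a round cross-section
    arc_r = 0.30 * min(extent[0], extent[1])
    tube_r = 0.14 * min(extent)
    arc_c = c + np.array([0.0, -0.15 * extent[1], 0.0])
    rho = np.sqrt((coords[..., 0] - arc_c[0]) ** 2 + (coords[..., 1] - arc_c[1]) ** 2)
    in_plane = np.abs(rho - arc_r)
    d2 = in_plane**2 + (coords[..., 2] - c[2]) ** 2
    front = coords[..., 1] >= arc_c[1]  # keep the arch half
    return (d2 <= tube_r**2) & front


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _draw_cut(rng, extent: np.ndarray, roughness: float) -> CutSurface:
    n = _random_unit(rng)
    point = extent / 2 + rng.uniform(-0.12, 0.12, size=3) * extent
    n_waves = 4
    # low-frequency waves with directions in the cut plane
    dirs = []
    for _ in range(n_waves):
        d = _random_unit(rng)
        d = d - (d @ n) * n
        nrm = np.linalg.norm(d)
        dirs.append(d / nrm if nrm > 1e-6 else _random_unit(rng))
    wavelength = rng.uniform(0.25, 0.6, size=n_waves) * float(np.min(extent))
    wavevectors = np.array([2 * np.pi / wl * d for wl, d in zip(wavelength, dirs)])
    amplitudes = np.full(n_waves, roughness / np.sqrt(n_waves))
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    return CutSurface(point, n, amplitudes, wavevectors, phases)


def _fragment_labels_from_cuts(intact: np.ndarray, cut_fields: list[np.ndarray]) -> np.ndarray:
    """Partition the intact mask by cut-field signs, then split into components."""
    region = np.zeros(intact.shape, dtype=np.int64)
    for b, g in enumerate(cut_fields):
        region |= (g > 0).astype(np.int64) << b
    labels = np.zeros(intact.shape, dtype=np.int32)
    nxt = 1
    struct = ndimage.generate_binary_structure(3, 3)
    for rid in np.unique(region[intact]):
        m = intact & (region == rid)
        lab, n = ndimage.label(m, structure=struct)
        for k in range(1, n + 1):
            labels[lab == k] = nxt
            nxt += 1
    return labels


def _displacement_for(rng, spec: PhantomSpec, centroid, outward) -> RigidTransform:
    angle = np.radians(rng.uniform(*spec.displacement_deg))
    axis = _random_unit(rng)
    mag = rng.uniform(*spec.displacement_mm)
    direction = outward + 0.5 * rng.normal(size=3)
    nrm = np.linalg.norm(direction)
    direction = direction / nrm if nrm > 1e-6 else _random_unit(rng)
    d = mag * direction
    rot = RigidTransform.from_axis_angle(axis, angle)
    # rotate about the fragment centroid, then translate by d
    t = centroid + d - rot.rotate_vectors(centroid)
    return RigidTransform(rot.quaternion, t)


def generate_phantom(spec: PhantomSpec, max_attempts: int = 50) -> PhantomTruth:
    """Generate a fractured phantom; retries with a derived sub-seed when a cut
    produces a fragment of fewer than 8 voxels."""
    spacing = np.asarray(spec.spacing, float)
    shape = tuple(spec.volume_shape)
    coords = _voxel_centers(shape, spacing)
    extent = np.asarray(shape) * spacing
    flat = coords.reshape(-1, 3)

    for attempt in range(max_attempts):
        rng = np.random.default_rng([spec.seed, attempt])
        intact_mask = _base_mask(spec, coords)
        cuts = [_draw_cut(rng, extent, spec.cut_roughness) for _ in range(spec.n_cuts)]
        cut_fields = [c.evaluate(flat).reshape(shape) for c in cuts]
        raw = _fragment_labels_from_cuts(intact_mask, cut_fields)

        if spec.erosion_voxels > 0:
            # compression-fracture damage: patches of the fracture face are
            # carved away to a depth of erosion_voxels, leaving pits whose
            # walls no longer anti-align with the mating face
            depth = spec.erosion_voxels * float(np.mean(spacing))
            damaged = np.zeros(shape, dtype=bool)
            for g in cut_fields:
                s = np.zeros(len(flat))
                for _ in range(4):
                    k = 2 * np.pi / (rng.uniform(0.15, 0.35) * float(np.min(extent)))
                    s += np.sin(flat @ (k * _random_unit(rng)) + rng.uniform(0, 2 * np.pi))
                damaged |= ((np.abs(g) < depth) & (s > 0).reshape(shape))
            raw = np.where(damaged, 0, raw)

        counts = np.bincount(raw.ravel())
        if len(counts) > 1 and counts[1:].min() < 8:
            logger.info("phantom attempt %d produced a <8-voxel fragment; retrying", attempt)
            continue
        n_frag = int((counts[1:] > 0).sum()) if len(counts) > 1 else 0
        if n_frag < spec.n_cuts + 1:
            # a cut missed the shape (or only clipped empty space): retry so
            # every requested cut actually fragments the phantom
            logger.info("phantom attempt %d: only %d fragments for %d cuts; retrying",
                        attempt, n_frag, spec.n_cuts)
            continue

        # relabel raw fragments compactly and deterministically
        # (descending size, ties by first voxel in C order)
        ids = [r for r in np.unique(raw) if r > 0]
        order = sorted(
            ids,
            key=lambda r: (-int(counts[r]), int(np.flatnonzero(raw.ravel() == r)[0])),
        )
        remap = np.zeros(int(raw.max()) + 1, dtype=np.int32)
        for new, r in enumerate(order, start=1):
            remap[r] = new
        intact_labels = remap[raw]
        intact_lv = LabeledVolume(intact_labels, spacing.copy(), np.zeros(3))

        ok, result = _displace(spec, attempt, intact_lv, coords, cuts)
        if ok:
            if spec.noise_components > 0:
                result.noise_mask = _noise_specks(spec, attempt, result.labeled)
            return result
        logger.info("phantom attempt %d: displaced fragment left the volume; retrying", attempt)
    raise RuntimeError(f"could not generate a valid phantom in {max_attempts} attempts")


def _displace(spec, attempt, intact_lv, coords, cuts):
    spacing = intact_lv.spacing
    shape = intact_lv.labels.shape
    extent = np.asarray(shape) * spacing
    center = extent / 2
    displaced = np.zeros(shape, dtype=np.int32)
    displacements: dict[int, RigidTransform] = {}
    truth: dict[int, RigidTransform] = {}
    single = len(intact_lv.label_ids) == 1
    for label in intact_lv.label_ids:
        m = intact_lv.labels == label
        if single:
            # an unfractured phantom stays in place: truth is the identity
            ident = RigidTransform.identity()
            displaced = np.where(m, int(label), displaced)
            displacements[int(label)] = ident
            truth[int(label)] = ident
            continue
        pts = coords[m]
        centroid = pts.mean(axis=0)
        outward = centroid - center
        nrm = np.linalg.norm(outward)
        outward = outward / nrm if nrm > 1e-6 else np.zeros(3)
        rng_f = np.random.default_rng([spec.seed, attempt, int(label)])
        occupied = ndimage.binary_dilation(
            displaced > 0, structure=ndimage.generate_binary_structure(3, 3)
        )
        placed = False
        for _ in range(20):
            D = _displacement_for(rng_f, spec, centroid, outward)
            moved = D.apply(pts)
            if not np.all((moved > 0.5 * spacing) & (moved < extent - 0.5 * spacing)):
                continue
            # nearest-neighbor resample of the fragment mask through D^-1
            Dinv = D.inverse()
            back = Dinv.apply(coords.reshape(-1, 3))
            ci = (back / spacing) - 0.5
            vals = ndimage.map_coordinates(m.astype(np.float32), ci.T, order=0, mode="constant")
            new_mask = (vals > 0.5).reshape(shape)
            # displaced fragments must stay separated (diastasis): connected-
            # component labeling is the stand-in for manual fragment splitting
            if (new_mask & occupied).any():
                continue
            placed = True
            break
        if not placed:
            return False, None
        displaced = np.where(new_mask, int(label), displaced)
        displacements[int(label)] = D
        truth[int(label)] = Dinv
    labeled = LabeledVolume(displaced, spacing.copy(), np.zeros(3))
    return True, PhantomTruth(
        spec=spec, labeled=labeled, intact=intact_lv,
        truth_poses=truth, displacements=displacements, cuts=cuts,
    )


def _noise_specks(spec: PhantomSpec, attempt: int, labeled: LabeledVolume) -> np.ndarray:
    """Connected background specks, each below 100 voxels, clear of the bone."""
    rng = np.random.default_rng([spec.seed, attempt, 991])
    shape = labeled.labels.shape
    bone = labeled.labels > 0
    keepout = ndimage.binary_dilation(bone, iterations=3)
    # ball offsets sorted by distance: taking the first n gives a connected blob
    r = 4
    offs = np.argwhere(np.ones((2 * r + 1,) * 3)) - r
    offs = offs[np.argsort(np.linalg.norm(offs, axis=1), kind="stable")]
    noise = np.zeros(shape, dtype=bool)
    for _ in range(spec.noise_components):
        size = int(rng.integers(spec.noise_size_range[0], spec.noise_size_range[1] + 1))
        for _try in range(200):
            c = rng.integers([r + 1] * 3, np.asarray(shape) - r - 1)
            vox = c + offs[:size]
            if not keepout[tuple(vox.T)].any() and not noise[tuple(vox.T)].any():
                noise[tuple(vox.T)] = True
                break
    return noise


def intensity_volume(
    pt: PhantomTruth, bone_value: float = 700.0, background: float = 0.0,
    include_noise: bool = True,
) -> IntensityVolume:
    """Render the displaced phantom as a CT-like intensity volume."""
    vox = np.full(pt.labeled.labels.shape, background, dtype=np.float64)
    vox[pt.labeled.labels > 0] = bone_value
    if include_noise and pt.noise_mask is not None:
        vox[pt.noise_mask] = bone_value
    return IntensityVolume(vox, pt.labeled.spacing.copy(), pt.labeled.origin.copy())


# ---------------------------------------------------------------------------
# Ground-truth fracture-face markings
# ---------------------------------------------------------------------------

def fracture_face_markings(
    pt: PhantomTruth,
    fragments: dict[int, Fragment],
    state: str = "displaced",
) -> list[tuple[MarkedSurface, MarkedSurface]]:
    """Marked-surface pairs for every mating face, from the generating cuts.

    For each cut and each adjacent fragment pair, marks the shell points lying
    within one voxel diagonal of the cut surface (evaluated in the intact
    frame, via the truth poses when the fragments were built from the
    displaced volume).
    """
    if state not in ("displaced", "intact"):
        raise ValueError("state must be 'displaced' or 'intact'")
    from scipy.spatial import cKDTree

    lv = pt.intact
    diag = float(np.linalg.norm(lv.spacing))
    # intact-frame shell points per fragment
    intact_pts = {}
    for label, frag in fragments.items():
        p = frag.shell.points
        intact_pts[label] = pt.truth_poses[label].apply(p) if state == "displaced" else p

    # per (a, b) pair: marked ids accumulated over all cuts they mate across
    merged: dict[tuple[int, int], tuple[list, list]] = {}
    for cut in pt.cuts:
        cand: dict[int, np.ndarray] = {}
        for label, frag in fragments.items():
            near = np.abs(cut.evaluate(intact_pts[label])) <= diag
            if near.sum() >= 5:
                cand[label] = near
        sides = {
            l: float(np.sign(np.mean(cut.evaluate(lv.voxel_centers_world(lv.labels == l)))))
            for l in cand
        }
        labels = sorted(cand)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if sides[a] == sides[b]:
                    continue
                pa, pb = intact_pts[a][cand[a]], intact_pts[b][cand[b]]
                # the mating interface: each side's candidates close to the other
                da, _ = cKDTree(pb).query(pa, k=1)
                db, _ = cKDTree(pa).query(pb, k=1)
                face_a, face_b = da <= 3 * diag, db <= 3 * diag
                n_a, n_b = int(face_a.sum()), int(face_b.sum())
                # demand substantial shared area: fragments that merely touch
                # along a cut-intersection line are not mates
                need = max(30, int(0.15 * min(cand[a].sum(), cand[b].sum())))
                if min(n_a, n_b) < need:
                    continue
                # and a tight interface: grazing near-contacts whose surfaces
                # pass within a few voxels without mating are rejected
                if (
                    np.median(da[face_a]) > diag
                    or np.median(db[face_b]) > diag
                ):
                    continue
                ids_a = fragments[a].shell.point_ids[cand[a]][face_a]
                ids_b = fragments[b].shell.point_ids[cand[b]][face_b]
                acc = merged.setdefault((a, b), ([], []))
                acc[0].append(ids_a)
                acc[1].append(ids_b)
    pairs = [
        (
            MarkedSurface(a, np.concatenate(ids_a)),
            MarkedSurface(b, np.concatenate(ids_b)),
        )
        for (a, b), (ids_a, ids_b) in sorted(merged.items())
    ]
    return pairs


# ---------------------------------------------------------------------------
# Scripted handle trajectories
# ---------------------------------------------------------------------------

def scripted_trajectories(
    pt: PhantomTruth,
    scenario: str,
    moving_label: int | None = None,
    static_label: int | None = None,
    offset_mm: float = 2.0,
    offset_deg: float = 5.0,
    n_samples: int = 25,
    fragments: dict[int, Fragment] | None = None,
) -> HandleTrajectory:
    """Deterministic handle scripts: approach_press, slide_along, coarse_align.

    ``coarse_align`` ends at a pose whose error against the truth pose is
    exactly (offset_mm, offset_deg), measured at the moving fragment centroid.
    """
    labels = sorted(int(l) for l in pt.labeled.label_ids)
    if moving_label is None:
        moving_label = labels[-1]
    if static_label is None:
        static_label = labels[0]
    rng = np.random.default_rng([pt.spec.seed, 7777])
    lv = pt.labeled
    cm = lv.voxel_centers_world(lv.labels == moving_label).mean(axis=0)
    cs = lv.voxel_centers_world(lv.labels == static_label).mean(axis=0)

    def _linear(start_t: np.ndarray, end_t: np.ndarray, start_q=None, end_q=None):
        from scipy.spatial.transform import Rotation, Slerp

        times = np.linspace(0.0, 1.0, n_samples)
        qs = None
        if start_q is not None:
            rots = Rotation.from_quat(
                [np.roll(start_q, -1), np.roll(end_q, -1)]
            )  # scalar-first -> scalar-last
            qs = Slerp([0.0, 1.0], rots)(times)
        samples = []
        for i, u in enumerate(times):
            t = (1 - u) * start_t + u * end_t
            if qs is None:
                pose = RigidTransform(translation=t)
            else:
                pose = RigidTransform.from_rotation(qs[i], t)
            samples.append((float(u), pose))
        return HandleTrajectory(samples)

    if scenario == "approach_press":
        # handle pose translation tracks the moving fragment pose (starts at identity);
        # drive it so the fragment centroid presses past the static surface
        to_static = cs - cm
        end = to_static * 1.1  # overshoot into the static fragment
        return _linear(np.zeros(3), end)
    if scenario == "slide_along":
        to_static = cs - cm
        n = to_static / np.linalg.norm(to_static)
        tang = _random_unit(rng)
        tang = tang - (tang @ n) * n
        tang /= np.linalg.norm(tang)
        mid = to_static * 1.05
        half = n_samples // 2
        a = _linear(np.zeros(3), mid)
        b = _linear(mid, mid + tang * 0.3 * np.linalg.norm(to_static))
        samples = [(t, p) for t, p in a.samples[:half]]
        samples += [(1.0 + t, p) for t, p in b.samples]
        # renumber times strictly increasing
        samples = [(i / (len(samples) - 1), p) for i, (_, p) in enumerate(samples)]
        return HandleTrajectory(samples)
    if scenario == "coarse_align":
        truth = pt.truth_poses[moving_label]
        frag_centroid = (
            fragments[moving_label].centroid if fragments else
            lv.voxel_centers_world(lv.labels == moving_label).mean(axis=0)
        )
        c_truth = truth.apply(frag_centroid)
        rot = RigidTransform.from_axis_angle(_random_unit(rng), np.radians(offset_deg))
        # rotate about the truth centroid, then translate by offset_mm
        t = c_truth - rot.rotate_vectors(c_truth)
        about = RigidTransform(rot.quaternion, t)
        shift = RigidTransform(translation=offset_mm * _random_unit(rng))
        end = compose(shift, compose(about, truth))
        start = RigidTransform.identity()
        return _linear(start.translation, end.translation, start.quaternion, end.quaternion)
    raise ValueError(f"unknown scenario {scenario!r}")
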