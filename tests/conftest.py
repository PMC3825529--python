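import numpy as np
import pytest

import fragreduce as fr


def random_rigid(rng, max_t=10.0):
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return fr.RigidTransform.from_axis_angle(
        v, rng.uniform(0, np.pi), rng.uniform(-max_t, max_t, size=3)
    )


def coarse_start(truth, centroid, rng, mm=2.0, deg=5.0):
    """A pose whose error vs truth is exactly (mm, deg) at the fragment centroid."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    c_truth = truth.apply(centroid)
    rot = fr.RigidTransform.from_axis_angle(axis, np.radians(deg))
    about = fr.RigidTransform(rot.quaternion, c_truth - rot.rotate_vectors(c_truth))
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    shift = fr.RigidTransform(translation=mm * d)
    return fr.compose(shift, fr.compose(about, truth))


def flood_fill_label(mask, connectivity=26):
    """Independent BFS flood-fill labeling oracle (no scipy)."""
    from collections import deque
    from itertools import product

    offsets = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if (connectivity == 6 and order > 1) or (connectivity == 18 and order > 2):
            continue
        offsets.append(d)
    shape = mask.shape
    labels = np.zeros(shape, dtype=np.int32)
    nxt = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        nxt += 1
        q = deque([start])
        labels[start] = nxt
        while q:
            x, y, z = q.popleft()
            for dx, dy, dz in offsets:
                n = (x + dx, y + dy, z + dz)
                if (
                    0 <= n[0] < shape[0] and 0 <= n[1] < shape[1] and 0 <= n[2] < shape[2]
                    and mask[n] and not labels[n]
                ):
                    labels[n] = nxt
                    q.append(n)
    return labels, nxt


@pytest.fixture(scope="session")
def wall_cube_volume():
    """A flat static wall (label 1) and a free cube (label 2), 1 mm spacing."""
    lab = np.zeros((40, 20, 20), dtype=np.int32)
    lab[2:8, 2:18, 2:18] = 1
    lab[20:30, 5:15, 5:15] = 2
    return fr.LabeledVolume(lab, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


@pytest.fixture()
def wall_cube_fragments(wall_cube_volume):
    return fr.build_fragments(wall_cube_volume)


@pytest.fixture(scope="session")
def phantom_one_cut():
    """Session-cached single-cut phantom at default study conditions."""
    pt = fr.generate_phantom(fr.PhantomSpec(seed=11, n_cuts=1))
    frags = fr.build_fragments(pt.labeled)
    return pt, frags
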