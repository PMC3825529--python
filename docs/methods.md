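# Methods

This note documents the models, numerical choices, and known limits of
`fragreduce`. All world coordinates are millimeters; voxel index `i` on an
axis with spacing `s` and origin `o` maps to the voxel-center coordinate
`o + (i + 0.5)·s`. Quaternions are scalar-first, unit, active; `q` and `−q`
are treated as the same rotation everywhere.

## Segmentation pre-processing

Bone is thresholded (`intensity ≥ threshold`; the threshold is a required
parameter — there is no universal Hounsfield cutoff across scanners and
reconstruction kernels). Connected components smaller than `min_size`
(default 100) voxels are removed with strictly-less-than semantics: a
component of exactly 100 voxels survives. Component analysis defaults to
26-connectivity and is configurable (6/18/26). Labeling orders components by
descending size with ties broken by the first voxel in C order, so label maps
are deterministic.

I/O: NIfTI and NRRD via SimpleITK; DICOM series are read with pydicom, sorted
by slice position, and a hard error names the offending slice pair when the
inter-slice spacing is inconsistent (e.g. a missing slice).

## Distance fields and point shells

Each fragment is pre-processed once, in its local frame, so poses never
trigger recomputation:

* **Signed distance field.** Two Euclidean distance transforms
  (scipy, anisotropic sampling) give center-to-center distances, which
  overshoot the true surface distance by about half a voxel. Each voxel is
  corrected by half the spacing along the dominant axis of its
  nearest-surface offset, making the field ~exact near flat faces (an 11³
  cube at 1 mm spacing reads −5.5 mm at its center) and keeping |∇φ| ≈ 1 at
  the surface. Sampling is trilinear; queries outside the grid return +inf.
* **Gradients.** The gradient grid is computed from a Gaussian-smoothed copy
  of the field (σ = 1.2 voxels). The half-voxel correction leaves sub-voxel
  ripple whose raw central differences tilt normals by up to ~15° on oblique
  surfaces; smoothing brings sphere-phantom normals within 5° of radial at
  100% of shell points while leaving flat-face normals exact.
* **Point shell.** One point per surface voxel (a labeled voxel with a
  6-neighbor of different label), projected onto the zero level set by a few
  capped Newton steps along the gradient; the normal is the normalized
  gradient at the projected point, with a radial fallback where the gradient
  degenerates (single-voxel fragments). No decimation by default: full
  density maximizes contact fidelity at the scale of desk-top planning.

A KD-tree over the shell answers nearest-neighbor and radius queries exactly.

## Contact and the static virtual coupling

Contact is penalty-based: every moving shell point with φ < 0 in a static
fragment's field contributes force `k_c·(−φ)·n̂` along the static field's
outward gradient; forces and torques are summed about the moving fragment's
world centroid (the single torque reference everywhere). Pruning culls points
outside a static field's bounding box before sampling — outside the grid the
field reports "no penetration", so pruning is exact by construction, and the
test suite verifies pruned ≡ exhaustive to 1e-9 with identical contact sets.

The virtual coupling is a translational spring `k_t` (N/mm) on pose
translation and a rotational spring `k_r` (N·mm/rad) on the shortest-arc
axis-angle between fragment and handle rotations. The fragment pose is the
quasi-static equilibrium of coupling + contact, found by damped first-order
descent with diagonal preconditioning: translation steps divide the force by
`k_t + k_c·n_contacts` along the mean contact normal but only `k_t`
tangentially (so stiff contact states are stable while frictionless sliding
along a wall is not over-damped); rotation steps divide torque by
`k_r + k_c·n_contacts·r̄²`, with r̄² the mean squared shell moment arm. Steps
are capped at one voxel diagonal and 0.1 rad. Convergence is declared when
the residual force and torque fall below `tol·k_t` and `tol·k_r`
(`tol` = 1e-4, i.e. a 0.1 µm equivalent displacement); non-convergence
returns the best pose with a flag and never raises mid-trajectory.

Defaults: `k_t = 1` N/mm, `k_r = 100` N·mm/rad, `k_c = 50` N/mm per point.
Only the ratio `k_c/k_t` matters for the headline bound: pressing the handle
a depth `D` past a wall leaves at most `k_t·D/k_c` of penetration at
equilibrium (plus one interpolation voxel of field uncertainty) — 0.1 mm for
`D` = 5 mm at the default ratio. There is no inertia, damping tuned to human
perception, or simultaneous multi-body dynamics: one moving entity at a time.

## Snap-to-fit

Only painted shell points participate. Pairing is one-directional nearest
neighbor (moving → target) within a 5 mm capture radius, recomputed every
iteration; per pair the force is `k_a·w·(y − x)` with
`w = max(0, −n_x·n_y)^p`, `p = 2`. Mating fracture faces have opposing
outward normals, so `w` rejects same-side and perpendicular surfaces and
sharpens with `p`. The reported similarity is the mean `w` over active pairs.
`snap_to_fit` also accepts a list of target fragments (one marking each) and
pools their marked points — used when a fragment mates several already-placed
neighbors in a reconstruction.

During snap the contact penalty uses a dedicated, softer stiffness
(`contact_stiffness = 5` N/mm rather than the manipulation default 50): a
stiff penalty biases the snapped equilibrium outward by a sub-voxel standoff
(~0.3 mm at the CT spacing used here), while a soft one merely regularizes
interpenetration as attraction finds the fit. Descent uses the same damped
stepper as the contact module, with steps scaled by `k_a·n_pairs` (and the
marked moment arm for rotation). "Stable fit" means a local equilibrium:
re-running from a pose perturbed by ≤ 0.1 mm / 0.5° returns to the same pose,
which the tests assert; it is explicitly not a global optimum.

## Grouping and plans

A group stores, per member, a fixed local→group offset computed at attach
time so that attaching, detaching and group motion are exactly motion-free
(verified to 1e-9 over 10³ random operations). Detach leaves the fragment at
its current world pose. A group can be materialized as one rigid body (union
shell with offset point ids); intra-group contacts are skipped during group
manipulation. Plans (poses, groups, markings) serialize to versioned JSON
with explicit errors on version mismatch or truncation; the reduction report
measures per-fragment translation error at the fragment centroid (making it
independent of the local-frame origin) and shortest-arc rotation error.

## Phantom generator

The generator defines the study conditions and is first-class, tested code:

* Base shapes: cube (default), hollow ellipsoid shell, bent tube
  (mandible-like arch), voxelized at the CT spacing 0.35 × 0.35 × 0.60 mm on
  an 80³ grid (a ~18 × 18 × 31 mm fragment — the scale of a zygomatic or
  mandibular piece).
* Cuts: random planes perturbed by low-frequency sinusoidal roughness of
  amplitude 1.5 mm (wavelengths a quarter to over half the phantom extent),
  interdigitating the faces so a snapped fit has a unique local minimum —
  flat cuts leave in-plane translation unobservable.
* Displacements: per fragment, 1.5–4 mm roughly outward plus 3–12° about a
  random axis, redrawn until the displaced fragment stays inside the volume
  and clear of the others. The guaranteed diastasis is deliberate: connected
  component labeling stands in for the manual fragment splitting that real
  planning data receives, so displaced fragments must not merge.
* Compression damage (`erosion_voxels`): patches of the fracture face
  selected by a smooth random field are carved to the requested depth,
  removing surface and leaving pit walls that anti-align poorly — damaged
  faces converge with strictly lower similarity.
* Noise specks: connected background blobs below 100 voxels, kept ≥ 2 voxels
  clear of bone, for the size filter to remove.
* All randomness derives from the `PhantomSpec` seed: attempt `a` uses
  `default_rng([seed, a])`, per-fragment draws `default_rng([seed, a,
  label])`, so phantoms are bit-reproducible. Cuts that miss the shape or
  strand a fragment under 8 voxels trigger a retry with the next sub-seed.

Ground-truth fracture-face markings select shell points within one voxel
diagonal of the generating cut surface, restricted to the actual mating
interface (mutual proximity within 3 diagonals), requiring both substantial
shared area (≥ 15% of the smaller candidate set, ≥ 30 points) and a tight
interface (median point gap within one voxel diagonal) — this rejects
fragment pairs that merely graze along a cut-intersection line. Pairs mating
across several cuts get their markings merged.

What the phantoms do **not** emulate: CT noise and beam hardening, partial
volume effects, soft tissue, anatomically accurate bone shapes, and teeth.
Passing tests therefore demonstrate the geometric/numerical correctness of
the pipeline under realistic voxel anisotropy and fracture geometry, not
segmentation robustness on clinical scans.

## Problem sizes and accuracy envelope

The default suite and the acceptance script use 80³ phantoms (unit tests use
48³ where geometry suffices, and the pruning study 32³), 20 phantom seeds for
the recovery study and one seeded end-to-end closure — sizes chosen so the
full pipeline exercises anisotropy and multi-fragment assembly while a
complete run stays in the minutes range on one CPU.

Known limits: snap equilibria on resampled (displaced-then-relabeled)
fragments carry a sub-voxel bias — typically ~0.2 mm translation and well
under 1° rotation, but individual faces whose geometry weakly constrains one
rotation axis can settle 1–1.5° off, so multi-fragment closures occasionally
exceed 1° RMS rotation for unlucky seeds. Using both mating faces of a
fragment and a final re-snap sweep (as the end-to-end study does) reduces but
does not eliminate this. Thin or very small fragments (few hundred shell
points) give the least robust snaps, mirroring the behavior expected of
attraction forces computed from small surfaces.
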