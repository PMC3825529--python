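"""CT pre-processing: bone thresholding, small-component removal, labeling, volume I/O.

The pipeline mirrors standard bone-segmentation practice for fracture planning:
threshold the intensity volume to separate bone from soft tissue, drop isolated
specks with fewer than ``min_size`` connected voxels (components of exactly
``min_size`` voxels survive), then assign each remaining connected component a
fragment label.

Volumes are stored with axis order ``(x, y, z)`` and physical metadata
(per-axis spacing in mm, world origin in mm). Anisotropic spacing — e.g. CT
with 0.35 mm in-plane resolution and 0.60 mm slice distance — is preserved
through every step and honored by all downstream physics.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

logger = logging.getLogger(__name__)

#: 3-D neighborhood structures by connectivity (face / face+edge / face+edge+corner)
_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _check_geometry(spacing, origin):
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if spacing.shape != (3,) or origin.shape != (3,):
        raise ValueError("spacing and origin must be 3-vectors")
    if np.any(spacing <= 0):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return spacing, origin


@dataclass
class IntensityVolume:
    """Scalar (Hounsfield-like) voxel grid with physical geometry."""

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        self.spacing, self.origin = _check_geometry(self.spacing, self.origin)


@dataclass
class LabeledVolume:
    """Integer voxel grid: 0 = background, labels 1..K = bone fragments."""

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing, self.origin = _check_geometry(self.spacing, self.origin)

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def voxel_centers_world(self, mask: np.ndarray) -> np.ndarray:
        """World (mm) centers of the voxels selected by a boolean mask."""
        idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.spacing


def threshold_bone(v: IntensityVolume, threshold: float) -> np.ndarray:
    """Binary bone mask: voxel is bone iff its intensity >= threshold."""
    vox = v.voxels
    if not np.all(np.isfinite(vox)):
        raise ValueError("intensity volume contains non-finite values")
    lo, hi = float(vox.min()), float(vox.max())
    if threshold > hi or threshold <= lo:
        logger.warning(
            "threshold %g outside volume value range [%g, %g]; mask will be empty or full",
            threshold, lo, hi,
        )
    return vox >= threshold


def remove_small_components(
    mask: np.ndarray, min_size: int = 100, connectivity: int = 26
) -> np.ndarray:
    """Drop connected components with fewer than ``min_size`` voxels.

    A component of exactly ``min_size`` voxels is retained (strictly-less-than
    removal). Idempotent.
    """
    struct = _STRUCTS[connectivity]
    lab, n = ndimage.label(mask, structure=struct)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(lab.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[lab]


def label_components(mask: np.ndarray, connectivity: int = 26, spacing=None, origin=None) -> LabeledVolume:
    """Label connected components 1..K, ordered by descending size.

    Ties are broken by the lexicographically first voxel index of the
    component, so the labeling is deterministic.
    """
    struct = _STRUCTS[connectivity]
    lab, n = ndimage.label(mask, structure=struct)
    out = np.zeros_like(lab, dtype=np.int32)
    if n > 0:
        counts = np.bincount(lab.ravel())[1:]
        # first voxel (in C order) per raw label, for tie-breaking
        flat = lab.ravel()
        first = np.full(n + 1, flat.size, dtype=np.int64)
        nz = np.flatnonzero(flat)
        # reversed so earlier indices overwrite later ones
        first[flat[nz[::-1]]] = nz[::-1]
        order = sorted(range(1, n + 1), key=lambda r: (-counts[r - 1], first[r]))
        remap = np.zeros(n + 1, dtype=np.int32)
        for new, raw in enumerate(order, start=1):
            remap[raw] = new
        out = remap[lab]
    spacing = np.ones(3) if spacing is None else spacing
    origin = np.zeros(3) if origin is None else origin
    return LabeledVolume(out, spacing, origin)


def segment_fragments(
    v: IntensityVolume, threshold: float, min_size: int = 100, connectivity: int = 26
) -> LabeledVolume:
    """threshold → small-component filter → labeling, in one call."""
    mask = threshold_bone(v, threshold)
    mask = remove_small_components(mask, min_size=min_size, connectivity=connectivity)
    lv = label_components(mask, connectivity=connectivity, spacing=v.spacing, origin=v.origin)
    return lv


# ---------------------------------------------------------------------------
# I/O — NIfTI / NRRD via SimpleITK, DICOM series via pydicom
# ---------------------------------------------------------------------------

def _from_sitk(img: sitk.Image):
    arr = sitk.GetArrayFromImage(img)          # (z, y, x)
    vox = np.transpose(arr, (2, 1, 0))         # -> (x, y, z)
    return vox, np.asarray(img.GetSpacing(), float), np.asarray(img.GetOrigin(), float)


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(voxels, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _read_dicom_series(path: str) -> IntensityVolume:
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append((f, ds))
    if not slices:
        raise ValueError(f"no DICOM image slices found in {path}")
    slices.sort(key=lambda fd: float(fd[1].ImagePositionPatient[2]))
    zpos = np.array([float(ds.ImagePositionPatient[2]) for _, ds in slices])
    if len(slices) > 1:
        dz = np.diff(zpos)
        if np.any(dz <= 0):
            raise ValueError("duplicate DICOM slice positions")
        ref = np.median(dz)
        bad = np.flatnonzero(np.abs(dz - ref) > 1e-3 * max(1.0, ref))
        if bad.size:
            names = ", ".join(
                f"{os.path.basename(slices[i][0])} -> {os.path.basename(slices[i + 1][0])}"
                f" (gap {dz[i]:.4f} mm, expected {ref:.4f} mm)"
                for i in bad
            )
            raise ValueError(f"inconsistent DICOM slice spacing between slices: {names}")
        slice_spacing = float(ref)
    else:
        slice_spacing = float(getattr(slices[0][1], "SliceThickness", 1.0))
    ds0 = slices[0][1]
    px = [float(x) for x in ds0.PixelSpacing]  # (row, col) = (y, x)
    planes = []
    for _, ds in slices:
        a = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(a * slope + inter)  # (rows=y, cols=x)
    vol = np.stack(planes, axis=-1)           # (y, x, z)
    vox = np.transpose(vol, (1, 0, 2))        # (x, y, z)
    origin = np.array(
        [float(ds0.ImagePositionPatient[0]), float(ds0.ImagePositionPatient[1]), zpos[0]]
    )
    spacing = np.array([px[1], px[0], slice_spacing])
    return IntensityVolume(vox, spacing, origin)


def read_volume(path: str, fmt: str | None = None) -> IntensityVolume:
    """Read a DICOM series directory, NIfTI (.nii/.nii.gz), or NRRD volume."""
    if fmt is None:
        fmt = "dicom-dir" if os.path.isdir(path) else (
            "nifti" if path.endswith((".nii", ".nii.gz")) else "nrrd"
        )
    if fmt == "dicom-dir":
        return _read_dicom_series(path)
    vox, spacing, origin = _from_sitk(sitk.ReadImage(path))
    return IntensityVolume(vox.astype(np.float64), spacing, origin)


def read_labels(path: str) -> LabeledVolume:
    """Read a label map (NIfTI or NRRD)."""
    vox, spacing, origin = _from_sitk(sitk.ReadImage(path))
    return LabeledVolume(np.rint(vox).astype(np.int32), spacing, origin)


def write_labels(lv: LabeledVolume, path: str) -> None:
    """Write a label map as NIfTI or NRRD (by file extension)."""
    sitk.WriteImage(_to_sitk(lv.labels.astype(np.int32), lv.spacing, lv.origin), path)


def write_volume(v: IntensityVolume, path: str) -> None:
    sitk.WriteImage(_to_sitk(v.voxels.astype(np.float64), v.spacing, v.origin), path)
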