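"""NIfTI volume I/O and grid resampling.

Volumes live in memory as ``(z, y, x)`` arrays — slices are the outer loop
of the sliding-window predictor — with spacing given as ``(sx, sy, sz)`` in
mm. On disk the canonical format is NIfTI (.nii/.nii.gz) whose affine
carries spacing, origin and orientation; nibabel handles the container.

CT intensities are Hounsfield Units clamped on ingest to the 12-bit scanner
range [−1024, 3071]. Label maps hold classes 0 (background), 1 (right
lobe), 2 (left lobe) plus a reserved ignore value (255) marking voxels
excluded from loss and evaluation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

HU_MIN = -1024.0
HU_MAX = 3071.0

BACKGROUND = 0
RIGHT_LOBE = 1
LEFT_LOBE = 2
IGNORE_LABEL = 255

CLASS_MAP = {BACKGROUND: "background", RIGHT_LOBE: "right_lobe", LEFT_LOBE: "left_lobe"}


class VolumeError(ValueError):
    """Raised for malformed volumes or metadata."""


@dataclasses.dataclass
class CTVolume:
    """A CT scan: HU voxel grid in (z, y, x) order plus physical metadata.

    spacing is (sx, sy, sz) in mm, origin (ox, oy, oz) in mm, direction a
    3x3 orientation matrix in world (x, y, z) axis order.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise VolumeError(f"expected a 3D (z, y, x) grid, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be three positive mm values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent per axis in (z, y, x) order."""
        nz, ny, nx = self.voxels.shape
        sx, sy, sz = self.spacing
        return (nz * sz, ny * sy, nx * sx)


@dataclasses.dataclass
class LabelVolume:
    """Integer class map aligned voxel-for-voxel with a CTVolume."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(3))
    ignore_value: int = IGNORE_LABEL
    class_map: dict = dataclasses.field(default_factory=lambda: dict(CLASS_MAP))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeError("label maps must have an integer dtype")
        self.labels = self.labels.astype(np.uint8, copy=False)
        if self.labels.ndim != 3:
            raise VolumeError(f"expected a 3D (z, y, x) grid, got shape {self.labels.shape}")
        allowed = set(self.class_map) | {self.ignore_value}
        present = set(np.unique(self.labels).tolist())
        if not present <= allowed:
            raise VolumeError(f"unexpected label values {sorted(present - allowed)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def _affine_from_meta(spacing, origin, direction) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.asarray(direction) @ np.diag(spacing)
    affine[:3, 3] = origin
    return affine


def _meta_from_affine(affine: np.ndarray):
    rs = affine[:3, :3]
    spacing = np.linalg.norm(rs, axis=0)
    if not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
        raise VolumeError("affine has zero or non-finite column norms")
    direction = rs / spacing
    if abs(np.linalg.det(direction)) < 1e-6:
        raise VolumeError("singular orientation matrix in affine")
    return tuple(spacing.tolist()), tuple(affine[:3, 3].tolist()), direction


def _load(path) -> tuple[np.ndarray, tuple, tuple, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(f"{path}: expected a 3D image, got {data.ndim} axes")
    spacing, origin, direction = _meta_from_affine(img.affine)
    # nibabel arrays are (x, y, z); working order is (z, y, x)
    return np.ascontiguousarray(data.transpose(2, 1, 0)), spacing, origin, direction


def read_volume(path) -> CTVolume:
    """Read a CT NIfTI file, clamping intensities to the 12-bit HU range."""
    data, spacing, origin, direction = _load(path)
    voxels = np.clip(data.astype(np.float32), HU_MIN, HU_MAX)
    return CTVolume(voxels, spacing, origin, direction)


def read_labelmap(path) -> LabelVolume:
    """Read an integer label map from NIfTI."""
    data, spacing, origin, direction = _load(path)
    return LabelVolume(np.rint(data).astype(np.uint8), spacing, origin, direction)


def _save(array_zyx: np.ndarray, spacing, origin, direction, path) -> None:
    affine = _affine_from_meta(spacing, origin, direction)
    img = nib.Nifti1Image(np.ascontiguousarray(array_zyx.transpose(2, 1, 0)), affine)
    nib.save(img, str(path))


def write_volume(v: CTVolume, path) -> None:
    _save(v.voxels.astype(np.float32), v.spacing, v.origin, v.direction, path)


def write_labelmap(lv: LabelVolume, path) -> None:
    """Write a label map as unsigned 8-bit NIfTI (lossless round trip)."""
    _save(lv.labels.astype(np.uint8), lv.spacing, lv.origin, lv.direction, path)


def _is_label(v) -> bool:
    return isinstance(v, LabelVolume)


def _rebuild(v, array, spacing):
    if _is_label(v):
        return LabelVolume(array.astype(np.uint8), spacing, v.origin, v.direction,
                           ignore_value=v.ignore_value, class_map=dict(v.class_map))
    return CTVolume(array.astype(np.float32), spacing, v.origin, v.direction)


def resample_slice_thickness(v, target_sz: float):
    """Resample along z to a new slice thickness, preserving z extent.

    Intensity volumes are linearly interpolated; label maps use
    nearest-neighbour so no new label values can appear.
    """
    if target_sz <= 0:
        raise ValueError(f"target slice thickness must be positive, got {target_sz}")
    sx, sy, sz = v.spacing
    arr = v.labels if _is_label(v) else v.voxels
    if abs(sz - target_sz) < 1e-9:
        return _rebuild(v, arr.copy(), v.spacing)
    nz = arr.shape[0]
    new_nz = max(1, int(round(nz * sz / target_sz)))
    order = 0 if _is_label(v) else 1
    out = ndimage.zoom(arr.astype(np.float32), (new_nz / nz, 1.0, 1.0),
                       order=order, mode="nearest", grid_mode=True)
    if _is_label(v):
        out = np.rint(out)
    return _rebuild(v, out, (sx, sy, target_sz))


def resample_axial(v, size: tuple[int, int]):
    """Resample each axial slice to ``(rows, cols)``, conserving physical extent."""
    rows, cols = int(size[0]), int(size[1])
    if rows < 1 or cols < 1:
        raise ValueError(f"axial size must be >= 1 per axis, got {size}")
    arr = v.labels if _is_label(v) else v.voxels
    nz, ny, nx = arr.shape
    sx, sy, sz = v.spacing
    if (ny, nx) == (rows, cols):
        return _rebuild(v, arr.copy(), v.spacing)
    order = 0 if _is_label(v) else 1
    out = ndimage.zoom(arr.astype(np.float32), (1.0, rows / ny, cols / nx),
                       order=order, mode="nearest", grid_mode=True)
    if _is_label(v):
        out = np.rint(out)
    new_spacing = (sx * nx / cols, sy * ny / rows, sz)
    return _rebuild(v, out, new_spacing)
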