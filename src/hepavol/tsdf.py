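"""Truncated signed distance field (t-SDF) regression targets.

For each foreground class the label map is turned into a per-voxel signed
distance to the class boundary: positive inside the class, negative
outside, measured in mm with anisotropic voxel spacing respected. The
convention is voxel-center: an inside voxel's distance is the Euclidean
distance to the center of the nearest outside voxel, and vice versa, so a
voxel adjacent to the boundary already carries |d| = one voxel pitch.
Distances are clipped to ±25 mm and rescaled to [−1, 1]; regressing this
band rather than unbounded distances suits the limited receptive field of
a convolutional network. A class absent from the volume yields an all −1
channel (everything maximally outside).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, RIGHT_LOBE, LEFT_LOBE

DEFAULT_TRUNCATION_MM = 25.0
FOREGROUND_CLASSES = (RIGHT_LOBE, LEFT_LOBE)


class DegenerateMaskError(ValueError):
    """Signed distance is undefined for an all-inside or all-outside mask."""


@dataclasses.dataclass
class TSDFVolume:
    """Per-class truncated signed distance targets, (class, z, y, x) in [−1, 1]."""

    fields: np.ndarray
    spacing: tuple[float, float, float]
    truncation_mm: float = DEFAULT_TRUNCATION_MM
    classes: tuple[int, ...] = FOREGROUND_CLASSES

    def __post_init__(self):
        self.fields = np.asarray(self.fields, dtype=np.float64)
        if self.fields.ndim != 4:
            raise ValueError(f"expected (class, z, y, x), got shape {self.fields.shape}")
        if self.fields.shape[0] != len(self.classes):
            raise ValueError("one field per foreground class is required")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fields.shape[1:]


def signed_edt(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance transform in mm on an anisotropic grid.

    ``spacing`` is (sx, sy, sz) while the mask is (z, y, x); inside voxels
    get +distance to the nearest outside voxel center, outside voxels
    −distance to the nearest inside voxel center.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError(f"expected a 3D mask, got shape {mask.shape}")
    if not mask.any() or mask.all():
        raise DegenerateMaskError("mask must contain both inside and outside voxels")
    sx, sy, sz = (float(s) for s in spacing)
    sampling = (sz, sy, sx)  # axis order (z, y, x)
    inside = ndimage.distance_transform_edt(mask, sampling=sampling)
    outside = ndimage.distance_transform_edt(~mask, sampling=sampling)
    return np.where(mask, inside, -outside)


def truncate_rescale(d: np.ndarray, t_mm: float = DEFAULT_TRUNCATION_MM) -> np.ndarray:
    """Clip distances to ±t_mm and rescale to [−1, 1]."""
    if t_mm <= 0:
        raise ValueError(f"truncation must be positive, got {t_mm}")
    return np.clip(np.asarray(d, dtype=np.float64), -t_mm, t_mm) / t_mm


def compute_tsdf(lv: LabelVolume, truncation_mm: float = DEFAULT_TRUNCATION_MM,
                 classes: tuple[int, ...] = FOREGROUND_CLASSES) -> TSDFVolume:
    """Build the t-SDF target stack from a multi-class label map.

    Ignore-labelled voxels carry no class and therefore count as background
    for distance purposes; their exclusion from the loss happens in the
    loss functions, not here.
    """
    fields = np.empty((len(classes),) + lv.labels.shape, dtype=np.float64)
    for i, c in enumerate(classes):
        mask = lv.labels == c
        if not mask.any():
            fields[i] = -1.0
        elif mask.all():
            fields[i] = 1.0
        else:
            fields[i] = truncate_rescale(signed_edt(mask, lv.spacing), truncation_mm)
    return TSDFVolume(fields, lv.spacing, truncation_mm, tuple(classes))
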