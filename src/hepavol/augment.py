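"""Seeded training-time augmentation: axial rotation, per-axis scale, crop.

The three transforms run in a fixed order — rotate, scale, crop — with one
seeded generator driving all random draws, so an augmentation pipeline is
fully reproducible. Image channels and t-SDF targets are interpolated
linearly, labels with nearest-neighbour; the transformed t-SDF is the
interpolated original field rather than a recomputation from the
transformed labels (scale factors ≤ 1.2 distort distances by ≤ 20%,
accepted as augmentation noise). Out-of-field voxels are filled with −1
in image/t-SDF space (air after windowing, maximally-outside distance)
and 0 (background) in label space.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

IMG_FILL = -1.0
TSDF_FILL = -1.0
LABEL_FILL = 0


@dataclasses.dataclass
class AugmentSpec:
    rotation_deg: float = 10.0  # symmetric bound: angle ~ U(−b, +b)
    scale_low: float = 0.8
    scale_high: float = 1.2
    crop_size: tuple[int, int, int] = (32, 128, 128)

    def __post_init__(self):
        if self.rotation_deg < 0:
            raise ValueError("rotation bound must be >= 0")
        if not 0 < self.scale_low <= self.scale_high:
            raise ValueError("scale bounds must be positive with low <= high")
        if min(self.crop_size) < 1:
            raise ValueError("crop dims must be >= 1")


def _check_aligned(img, labels, tsdf):
    if img.ndim != 4 or tsdf.ndim != 4 or labels.ndim != 3:
        raise ValueError("expected img (c,z,y,x), labels (z,y,x), tsdf (c,z,y,x)")
    if img.shape[1:] != labels.shape or tsdf.shape[1:] != labels.shape:
        raise ValueError(
            f"misaligned shapes: img {img.shape[1:]}, labels {labels.shape}, "
            f"tsdf {tsdf.shape[1:]}")


def random_rotate(img, labels, tsdf, rng: np.random.Generator,
                  max_deg: float = 10.0, angle: float | None = None):
    """Rotate all inputs in the axial (y, x) plane by one shared angle."""
    _check_aligned(img, labels, tsdf)
    if angle is None:
        angle = float(rng.uniform(-max_deg, max_deg))
    if angle == 0.0:
        return img.copy(), labels.copy(), tsdf.copy()
    rot = lambda a, order, cval: ndimage.rotate(
        a, angle, axes=(-2, -1), reshape=False, order=order, mode="constant", cval=cval)
    img_r = np.stack([rot(c, 1, IMG_FILL) for c in img]).astype(np.float32)
    tsdf_r = np.stack([rot(c, 1, TSDF_FILL) for c in tsdf]).astype(np.float32)
    lab_r = rot(labels.astype(np.float32), 0, LABEL_FILL)
    return img_r, np.rint(lab_r).astype(labels.dtype), np.clip(tsdf_r, -1.0, 1.0)


def random_scale(img, labels, tsdf, rng: np.random.Generator,
                 low: float = 0.8, high: float = 1.2, factors=None):
    """Scale with three independent uniform per-axis factors, shared by all inputs."""
    _check_aligned(img, labels, tsdf)
    if factors is None:
        factors = tuple(float(f) for f in rng.uniform(low, high, size=3))
    if factors == (1.0, 1.0, 1.0):
        return img.copy(), labels.copy(), tsdf.copy()
    fz, fy, fx = factors
    zoom = lambda a, order: ndimage.zoom(a, (fz, fy, fx), order=order,
                                         mode="nearest", grid_mode=True)
    img_s = np.stack([zoom(c, 1) for c in img]).astype(np.float32)
    tsdf_s = np.stack([zoom(c, 1) for c in tsdf]).astype(np.float32)
    lab_s = zoom(labels.astype(np.float32), 0)
    return img_s, np.rint(lab_s).astype(labels.dtype), np.clip(tsdf_s, -1.0, 1.0)


def _pad_to(a, target_shape, fill, spatial_from: int):
    pads = [(0, 0)] * spatial_from
    for s, t in zip(a.shape[spatial_from:], target_shape):
        short = max(0, t - s)
        pads.append((short // 2, short - short // 2))
    if any(p != (0, 0) for p in pads):
        a = np.pad(a, pads, constant_values=fill)
    return a


def random_crop(img, labels, tsdf, crop_size, rng: np.random.Generator,
                offset=None):
    """Crop all inputs to ``crop_size`` at one shared random offset.

    Inputs smaller than the crop are first centre-padded (image/t-SDF
    with −1, labels with background).
    """
    _check_aligned(img, labels, tsdf)
    crop_size = tuple(int(c) for c in crop_size)
    img = _pad_to(img, crop_size, IMG_FILL, 1)
    tsdf = _pad_to(tsdf, crop_size, TSDF_FILL, 1)
    labels = _pad_to(labels, crop_size, LABEL_FILL, 0)
    shape = labels.shape
    if offset is None:
        offset = tuple(int(rng.integers(0, shape[i] - crop_size[i] + 1))
                       for i in range(3))
    sl = tuple(slice(o, o + c) for o, c in zip(offset, crop_size))
    return (np.ascontiguousarray(img[(slice(None),) + sl]),
            np.ascontiguousarray(labels[sl]),
            np.ascontiguousarray(tsdf[(slice(None),) + sl]))


def augment_triple(img, labels, tsdf, spec: AugmentSpec, rng: np.random.Generator):
    """The full pipeline in fixed order: rotate → scale → crop."""
    img, labels, tsdf = random_rotate(img, labels, tsdf, rng, spec.rotation_deg)
    img, labels, tsdf = random_scale(img, labels, tsdf, rng, spec.scale_low,
                                     spec.scale_high)
    return random_crop(img, labels, tsdf, spec.crop_size, rng)
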