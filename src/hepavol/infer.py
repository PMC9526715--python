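"""Sliding-window inference with z-weighted aggregation and fold ensembling.

Variable-length volumes are predicted crop by crop along z with 75%
overlap. Each crop's probabilities are blended with a per-slice weight
profile — full weight on the central plateau, a linear taper to nearly
(never exactly) zero on the margins — so crop-edge predictions, which see
truncated context, contribute little where a better-centred crop is
available. Per-voxel accumulation divides by the summed weights and
renormalizes, so probabilities always sum to one. Cross-validation fold
models are fused late: their probability volumes are averaged.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .preprocess import MultiWindowVolume
from .volume_io import LabelVolume


@dataclasses.dataclass
class WeightProfile:
    """Per-slice aggregation weights for one crop: plateau + symmetric tapers."""

    weights: np.ndarray
    plateau: int
    taper: int

    @property
    def crop_z(self) -> int:
        return len(self.weights)


def make_weight_profile(crop_z: int = 32, plateau: int = 16, taper: int = 8,
                        shape: str = "linear") -> WeightProfile:
    """Build the aggregation profile; plateau + 2·taper must equal crop_z."""
    if plateau + 2 * taper != crop_z:
        raise ValueError(
            f"inconsistent geometry: plateau {plateau} + 2*taper {taper} != crop_z {crop_z}")
    if taper < 0 or plateau < 1:
        raise ValueError("plateau must be >= 1 and taper >= 0")
    w = np.ones(crop_z, dtype=np.float64)
    ramp = np.arange(1, taper + 1, dtype=np.float64) / (taper + 1)
    if shape == "cosine":
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, taper + 1) / (taper + 1)))
    elif shape != "linear":
        raise ValueError(f"unknown taper shape {shape!r}")
    w[:taper] = ramp
    w[crop_z - taper:] = ramp[::-1]
    return WeightProfile(w, plateau, taper)


def window_starts(n_slices: int, crop_z: int, overlap: float = 0.75) -> list[int]:
    """Start indices of the sliding windows, final window snapped to the end."""
    stride = max(1, int(round(crop_z * (1.0 - overlap))))
    if n_slices <= crop_z:
        return [0]
    starts = list(range(0, n_slices - crop_z + 1, stride))
    if starts[-1] != n_slices - crop_z:
        starts.append(n_slices - crop_z)
    return starts


@dataclasses.dataclass
class ProbabilityVolume:
    """Per-voxel class probabilities, (class, z, y, x), summing to 1."""

    probs: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 4:
            raise ValueError(f"expected (class, z, y, x), got {self.probs.shape}")


def _model_fn(model):
    """Accept either a fitted network or a plain callable crop → probs."""
    return model.predict if hasattr(model, "predict") else model


def sliding_window_predict(v: MultiWindowVolume, model, crop_z: int = 32,
                           overlap: float = 0.75,
                           profile: WeightProfile | None = None) -> ProbabilityVolume:
    """Predict a whole volume by weighted aggregation of overlapping z-crops.

    Volumes thinner than one crop are symmetrically padded (fill −1, air)
    to ``crop_z``, predicted in one window, and un-padded.
    """
    if profile is None:
        profile = make_weight_profile(crop_z, crop_z - 2 * (crop_z // 4), crop_z // 4)
    if profile.crop_z != crop_z:
        raise ValueError("weight profile length must equal crop_z")
    fn = _model_fn(model)
    channels = v.channels
    nz = channels.shape[1]
    pad = max(0, crop_z - nz)
    if pad:
        lo, hi = pad // 2, pad - pad // 2
        channels = np.pad(channels, ((0, 0), (lo, hi), (0, 0), (0, 0)),
                          constant_values=-1.0)
    nzp = channels.shape[1]

    acc = None
    wsum = np.zeros(nzp, dtype=np.float64)
    wz = profile.weights
    for s in window_starts(nzp, crop_z, overlap):
        crop = channels[:, s:s + crop_z]
        p = np.asarray(fn(crop), dtype=np.float64)
        if acc is None:
            acc = np.zeros((p.shape[0], nzp) + p.shape[2:], dtype=np.float64)
        acc[:, s:s + crop_z] += p * wz[None, :, None, None]
        wsum[s:s + crop_z] += wz
    probs = acc / wsum[None, :, None, None]
    probs /= probs.sum(axis=0, keepdims=True)
    if pad:
        probs = probs[:, pad // 2: pad // 2 + nz]
    return ProbabilityVolume(probs.astype(np.float32), v.spacing)


def ensemble_predict(v: MultiWindowVolume, models, crop_z: int = 32,
                     overlap: float = 0.75,
                     profile: WeightProfile | None = None) -> ProbabilityVolume:
    """Late fusion: average of the per-fold probability volumes, renormalized."""
    models = list(models)
    if not models:
        raise ValueError("at least one model is required")
    acc = None
    for m in models:
        pv = sliding_window_predict(v, m, crop_z, overlap, profile)
        acc = pv.probs.astype(np.float64) if acc is None else acc + pv.probs
    probs = acc / len(models)
    probs /= probs.sum(axis=0, keepdims=True)
    return ProbabilityVolume(probs.astype(np.float32), v.spacing)


def argmax_labels(p: ProbabilityVolume) -> LabelVolume:
    """Hard labels: per-voxel argmax, ties broken toward the lowest class id."""
    labels = np.argmax(p.probs, axis=0).astype(np.uint8)
    return LabelVolume(labels, p.spacing)
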