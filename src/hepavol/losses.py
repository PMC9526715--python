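"""Training objective: masked cross-entropy + generalized soft Dice + L1 t-SDF.

All three terms exclude ignore-labelled voxels from both value and
gradient. The generalized Dice term sums over every class including
background with class weights w_c = 1/(Σ_v g_cv)² (ε-guarded so absent
classes contribute negligibly instead of dividing by zero):

    GDL = 1 − 2·(Σ_c w_c Σ_v p_cv g_cv + ε) / (Σ_c w_c Σ_v (p_cv + g_cv) + ε)

The functions accept plain arrays (returning floats) or autodiff Tensors
(returning Tensors), so the same code path serves evaluation and the
training loop. Probability/label grids may be (C, z, y, x) or batched
(N, C, z, y, x).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .volume_io import LabelVolume, IGNORE_LABEL
from .tsdf import TSDFVolume

EPS_LOG = 1e-7
EPS_DICE = 1e-6


class LossUndefinedError(ValueError):
    """All voxels carry the ignore label: no loss term is defined."""


@dataclasses.dataclass(frozen=True)
class LossWeights:
    w_ce: float = 1.0
    w_dice: float = 1.0
    w_l1: float = 1.0

    def __post_init__(self):
        if min(self.w_ce, self.w_dice, self.w_l1) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.w_ce + self.w_dice + self.w_l1 <= 0:
            raise ValueError("at least one loss weight must be positive")


def _as_tensor5(x) -> tuple[Tensor, bool]:
    """Normalize probs/predictions to a 5D (N, C, z, y, x) Tensor."""
    was_tensor = isinstance(x, Tensor)
    t = x if was_tensor else Tensor(np.asarray(x, dtype=np.float32))
    if t.ndim == 4:
        t = ad.Tensor(t.data[None]) if not (t.requires_grad or t._parents) else _expand(t)
    if t.ndim != 5:
        raise ValueError(f"expected 4D or 5D field, got {t.ndim}D")
    return t, was_tensor


def _expand(t: Tensor) -> Tensor:
    def backward(g):
        ad._accum(t, g[0])
    return ad._node(t.data[None], (t,), backward)


def _labels4(lv, n_batch: int) -> np.ndarray:
    labels = lv.labels if isinstance(lv, LabelVolume) else np.asarray(lv)
    if labels.ndim == 3:
        labels = labels[None]
    if labels.shape[0] != n_batch:
        raise ValueError("label batch does not match prediction batch")
    return labels


def _ret(val: Tensor, as_tensor: bool):
    return val if as_tensor else float(val.data)


def masked_cross_entropy(probs, lv, ignore_value: int = IGNORE_LABEL):
    """Mean −log p(true class) over non-ignore voxels."""
    p, was_t = _as_tensor5(probs)
    labels = _labels4(lv, p.shape[0])
    n_classes = p.shape[1]
    valid = labels != ignore_value
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise LossUndefinedError("every voxel is ignore-labelled")
    onehot = np.stack([(labels == c) & valid for c in range(n_classes)],
                      axis=1).astype(np.float32)
    logp = ad.tlog(p + EPS_LOG)
    ce = ad.mul(ad.tsum(ad.mul(logp, onehot)), -1.0 / n_valid)
    return _ret(ce, was_t)


def generalized_soft_dice(probs, lv, ignore_value: int = IGNORE_LABEL):
    """Generalized soft Dice loss over all classes, ignore voxels excluded."""
    p, was_t = _as_tensor5(probs)
    labels = _labels4(lv, p.shape[0])
    n_classes = p.shape[1]
    valid = labels != ignore_value
    if not valid.any():
        raise LossUndefinedError("every voxel is ignore-labelled")
    mask = valid[:, None].astype(np.float32)
    onehot = np.stack([(labels == c) & valid for c in range(n_classes)],
                      axis=1).astype(np.float32)
    g_sums = onehot.sum(axis=(0, 2, 3, 4))
    w = 1.0 / (g_sums + EPS_DICE) ** 2  # constant w.r.t. predictions

    pm = ad.mul(p, mask)
    num_c = ad.tsum(ad.mul(pm, onehot), axis=(0, 2, 3, 4))
    den_c = ad.tsum(ad.add(pm, Tensor(onehot)), axis=(0, 2, 3, 4))
    num = ad.tsum(ad.mul(num_c, w))
    den = ad.tsum(ad.mul(den_c, w))
    loss = 1.0 - ad.div(ad.mul(num, 2.0) + EPS_DICE, den + EPS_DICE)
    return _ret(loss, was_t)


def l1_tsdf(pred, target, lv, ignore_value: int = IGNORE_LABEL):
    """Mean |pred − target| over all t-SDF channels and non-ignore voxels."""
    p, was_t = _as_tensor5(pred)
    tgt = target.fields if isinstance(target, TSDFVolume) else np.asarray(target)
    t5, _ = _as_tensor5(tgt)
    if p.shape != t5.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {t5.shape}")
    labels = _labels4(lv, p.shape[0])
    valid = labels != ignore_value
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise LossUndefinedError("every voxel is ignore-labelled")
    mask = valid[:, None].astype(np.float32)
    diff = ad.tabs(ad.add(p, ad.mul(t5, -1.0)))
    total = ad.tsum(ad.mul(diff, mask))
    return _ret(ad.mul(total, 1.0 / (n_valid * p.shape[1])), was_t)


def combined_loss(probs, tsdf_pred, lv, tsdf_target,
                  weights: LossWeights = LossWeights(),
                  ignore_value: int = IGNORE_LABEL):
    """w_ce·CE + w_dice·GDL + w_l1·L1, each term ignore-masked."""
    terms = []
    as_tensor = isinstance(probs, Tensor) or isinstance(tsdf_pred, Tensor)
    if weights.w_ce:
        terms.append(ad.mul(_t(masked_cross_entropy(probs, lv, ignore_value)), weights.w_ce))
    if weights.w_dice:
        terms.append(ad.mul(_t(generalized_soft_dice(probs, lv, ignore_value)), weights.w_dice))
    if weights.w_l1:
        terms.append(ad.mul(_t(l1_tsdf(tsdf_pred, tsdf_target, lv, ignore_value)), weights.w_l1))
    total = terms[0]
    for t in terms[1:]:
        total = ad.add(total, t)
    return total if as_tensor else float(total.data)


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.float32(x))
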