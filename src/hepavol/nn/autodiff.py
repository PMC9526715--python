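"""Minimal reverse-mode autodiff on NumPy arrays, sized for small 3D convnets.

A :class:`Tensor` wraps a float32 ndarray and records a backward closure
per producing op; ``Tensor.backward()`` runs the tape in reverse
topological order. The op set is exactly what a Multi-Resolution U-Net 3D
with instance normalization and dual heads needs: stride-1 same-padding
3D convolution (im2col + BLAS matmul), kernel==stride transposed
convolution for upsampling, non-overlapping max pooling with per-axis
factors, instance norm, ReLU/tanh/channel softmax, channel concatenation,
and broadcast-aware elementwise arithmetic/reductions for the losses.

Feature layout is (N, C, D, H, W) throughout. Gradient recording can be
switched off globally with :func:`no_grad` for inference.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ---- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- backward pass --------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ---- operators ------------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    g = g.astype(np.float32, copy=False)
    t.grad = g if t.grad is None else t.grad + g


def _node(data, parents, backward) -> Tensor:
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    if g.shape == tuple(shape):
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---- elementwise & reductions -------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _node(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data / b.data

    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _node(out_data, (a, b), backward)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(i % a.ndim for i in ax)
            shape = tuple(1 if i in ax else s for i, s in enumerate(a.shape))
            gg = gg.reshape(shape)
        _accum(a, np.broadcast_to(gg, a.shape).copy())

    return _node(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[i % a.ndim] for i in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def tabs(a: Tensor) -> Tensor:
    a = _wrap(a)
    out_data = np.abs(a.data)
    sign = np.sign(a.data)

    def backward(g):
        _accum(a, g * sign)

    return _node(out_data, (a,), backward)


def tlog(a: Tensor) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _node(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        _accum(a, g * mask)

    return _node(out_data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    a = _wrap(a)
    out_data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - out_data ** 2))

    return _node(out_data, (a,), backward)


def softmax_channels(a: Tensor) -> Tensor:
    """Softmax over the channel axis (axis 1) of an (N, C, ...) tensor."""
    a = _wrap(a)
    z = a.data - a.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        _accum(a, p * (g - dot))

    return _node(p, (a,), backward)


def concat_channels(tensors) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[1] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=1)

    def backward(g):
        ofs = 0
        for t, s in zip(tensors, sizes):
            _accum(t, g[:, ofs:ofs + s])
            ofs += s

    return _node(out_data, tuple(tensors), backward)


# ---- convolution / pooling / normalization ------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, D, H, W) → (N·D·H·W, C·k³) patch matrix with same padding."""
    p = k // 2
    n, c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    cols = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    return cols.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * d * h * w, c * k ** 3)


def _conv_raw(x: np.ndarray, w: np.ndarray, b=None, cols_out=None) -> np.ndarray:
    """Stride-1 same-padding correlation; optionally returns the patch matrix."""
    n, c, d, h, wd = x.shape
    co, ci, k = w.shape[0], w.shape[1], w.shape[2]
    cols = _im2col(x, k)
    out = cols @ w.reshape(co, -1).T
    if b is not None:
        out += b
    out = out.reshape(n, d, h, wd, co).transpose(0, 4, 1, 2, 3)
    if cols_out is not None:
        cols_out.append(cols)
    return np.ascontiguousarray(out)


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3D convolution, stride 1, same padding, odd cubic kernel."""
    x, w, b = _wrap(x), _wrap(w), _wrap(b)
    co, ci, k = w.shape[0], w.shape[1], w.shape[2]
    cache: list = []
    keep = _GRAD_ENABLED
    out_data = _conv_raw(x.data, w.data, b.data, cols_out=cache if keep else None)

    def backward(g):
        n, _, d, h, wd = g.shape
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(-1, co)
        _accum(b, gmat.sum(axis=0))
        _accum(w, (gmat.T @ cache[0]).reshape(w.shape))
        if x.requires_grad or x._parents:
            # dx: full correlation with channel-swapped, spatially flipped kernels
            w_rot = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
            _accum(x, _conv_raw(g, w_rot))

    return _node(out_data, (x, w, b), backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor, factor) -> Tensor:
    """Transposed convolution with kernel == stride == ``factor`` per axis.

    Each input voxel maps linearly onto a non-overlapping fz×fy×fx output
    block — the standard learned-upsampling choice mirroring the pooling.
    w has shape (C_in, C_out, fz, fy, fx).
    """
    x, w, b = _wrap(x), _wrap(w), _wrap(b)
    fz, fy, fx = factor
    n, ci, d, h, wd = x.shape
    co = w.shape[1]
    y = np.einsum("ncdhw,coijk->nodihjwk", x.data, w.data, optimize=True)
    y = y.reshape(n, co, d * fz, h * fy, wd * fx) + b.data.reshape(1, co, 1, 1, 1)

    def backward(g):
        g6 = g.reshape(n, co, d, fz, h, fy, wd, fx)
        _accum(b, g.sum(axis=(0, 2, 3, 4)))
        _accum(w, np.einsum("ncdhw,nodihjwk->coijk", x.data, g6, optimize=True))
        _accum(x, np.einsum("nodihjwk,coijk->ncdhw", g6, w.data, optimize=True))

    return _node(np.ascontiguousarray(y), (x, w, b), backward)


def maxpool3d(x: Tensor, factor) -> Tensor:
    """Non-overlapping max pooling with per-axis factors (dims must divide)."""
    x = _wrap(x)
    fz, fy, fx = factor
    n, c, d, h, w = x.shape
    if d % fz or h % fy or w % fx:
        raise ValueError(f"shape {(d, h, w)} not divisible by pooling {factor}")
    dp, hp, wp = d // fz, h // fy, w // fx
    blocks = (x.data.reshape(n, c, dp, fz, hp, fy, wp, fx)
              .transpose(0, 1, 2, 4, 6, 3, 5, 7)
              .reshape(n, c, dp, hp, wp, fz * fy * fx))
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gb = np.zeros((n, c, dp, hp, wp, fz * fy * fx), dtype=np.float32)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gx = (gb.reshape(n, c, dp, hp, wp, fz, fy, fx)
              .transpose(0, 1, 2, 5, 3, 6, 4, 7)
              .reshape(n, c, d, h, w))
        _accum(x, gx)

    return _node(np.ascontiguousarray(out_data), (x,), backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Instance normalization over spatial axes, per example and channel."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    sp = (2, 3, 4)
    mu = x.data.mean(axis=sp, keepdims=True)
    var = x.data.var(axis=sp, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xh = (x.data - mu) * inv
    gsh = gamma.data.reshape(1, -1, 1, 1, 1)
    out_data = gsh * xh + beta.data.reshape(1, -1, 1, 1, 1)

    def backward(g):
        _accum(gamma, (g * xh).sum(axis=(0, 2, 3, 4)))
        _accum(beta, g.sum(axis=(0, 2, 3, 4)))
        dxh = g * gsh
        m1 = dxh.mean(axis=sp, keepdims=True)
        m2 = (dxh * xh).mean(axis=sp, keepdims=True)
        _accum(x, inv * (dxh - m1 - xh * m2))

    return _node(out_data, (x, gamma, beta), backward)
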