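"""Layer/module system and the AdamW optimizer for the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: children and parameters are discovered via attributes."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for k, v in val.parameters().items():
                    out[f"{name}.{k}"] = v
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for k, v in item.parameters().items():
                            out[f"{name}.{i}.{k}"] = v
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != v.data.shape:
                raise ValueError(f"{k}: shape {arr.shape} != {v.data.shape}")
            v.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


class Conv3d(Module):
    """Stride-1 same-padding 3D convolution with an odd cubic kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        self.weight = _he_init(rng, (out_ch, in_ch, kernel, kernel, kernel),
                               in_ch * kernel ** 3)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias)


class ConvTranspose3d(Module):
    """Learned upsampling: kernel == stride == per-axis factor."""

    def __init__(self, in_ch: int, out_ch: int, factor, rng: np.random.Generator):
        self.factor = tuple(int(f) for f in factor)
        self.weight = _he_init(rng, (in_ch, out_ch) + self.factor, in_ch)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose3d(x, self.weight, self.bias, self.factor)


class InstanceNorm3d(Module):
    def __init__(self, ch: int):
        self.gamma = Tensor(np.ones(ch, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.instance_norm(x, self.gamma, self.beta)


_ACTIVATIONS = {"relu": ad.relu, "tanh": ad.tanh}


def activation_fn(name: str):
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}")


class AdamW:
    """Adam with decoupled weight decay.

    The decay multiplies the parameter directly each step, outside the
    adaptive gradient moments and independent of the learning rate — with
    lr = 0 and decay > 0, weights still shrink multiplicatively while no
    gradient step is taken.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = p.grad
            if g is not None:
                m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
                v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
                p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                p.data -= self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
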