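"""Multi-Resolution U-Net 3D with dual heads.

Encoder/decoder levels use MultiRes blocks: a 7×7×7 receptive field is
factorized into three successive 3×3×3 convolutions whose intermediate
outputs are concatenated along channels, normalized, and added to a 1×1×1
residual projection before the activation. The per-level channel budget W
is split across the three branches as (1/6, 1/3, 1/2)·W (rounded), and
skip connections pass through "res paths" — stacks of residual 3³ conv
units that narrow the semantic gap between encoder and decoder features,
with more units on shallower skips.

All normalization is instance norm, so the network trains with batch
size 1. Two 1×1×1 heads sit on the final decoder feature: a 3-class
softmax (background / right lobe / left lobe) and a tanh head regressing
the two truncated signed-distance channels.

Pooling is 2×2×2 between levels, except that the z axis stops being
pooled once the z extent of the configured training crop would drop below
8 slices (anisotropic 1×2×2 pooling at the deepest levels), so thin
axial crops survive deep networks.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Module, Conv3d, ConvTranspose3d, InstanceNorm3d, activation_fn


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class ModelConfig:
    in_channels: int = 3
    n_classes: int = 3
    n_tsdf_channels: int = 2
    depth: int = 5
    base_filters: int = 32
    alpha: float = 1.67
    activation: str = "relu"
    crop_z: int = 32  # reference z extent; fixes the z-pooling schedule

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigError("depth must be >= 2")
        if self.base_filters < 4:
            raise ConfigError("base_filters must be >= 4")
        if self.n_classes != 3 or self.in_channels != 3:
            raise ConfigError("the lobe segmentation task is 3-channel in, 3-class out")

    def level_budget(self, level: int) -> int:
        return int(round(self.alpha * self.base_filters * 2 ** level))

    def pool_factors(self) -> list[tuple[int, int, int]]:
        """Per-transition pooling factors; z pooled only while z extent >= 8."""
        factors = []
        z = self.crop_z
        for _ in range(self.depth - 1):
            fz = 2 if (z >= 8 and z % 2 == 0) else 1
            factors.append((fz, 2, 2))
            z //= fz
        return factors

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def branch_widths(width_budget: int) -> tuple[int, int, int]:
    """Split a MultiRes channel budget as (1/6, 1/3, 1/2), rounded."""
    if width_budget < 6:
        raise ConfigError(f"width budget {width_budget} cannot be split into three branches")
    w1 = max(1, round(width_budget / 6))
    w2 = max(1, round(width_budget / 3))
    w3 = max(1, round(width_budget / 2))
    return w1, w2, w3


class MultiResBlock3d(Module):
    """Three chained 3³ convolutions, concatenated, plus a 1³ residual path."""

    def __init__(self, in_ch: int, width_budget: int, activation: str,
                 rng: np.random.Generator):
        w1, w2, w3 = branch_widths(width_budget)
        self.out_ch = w1 + w2 + w3
        self.act = activation_fn(activation)
        self.conv1 = Conv3d(in_ch, w1, 3, rng)
        self.norm1 = InstanceNorm3d(w1)
        self.conv2 = Conv3d(w1, w2, 3, rng)
        self.norm2 = InstanceNorm3d(w2)
        self.conv3 = Conv3d(w2, w3, 3, rng)
        self.norm3 = InstanceNorm3d(w3)
        self.norm_cat = InstanceNorm3d(self.out_ch)
        self.shortcut = Conv3d(in_ch, self.out_ch, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        c1 = self.act(self.norm1(self.conv1(x)))
        c2 = self.act(self.norm2(self.conv2(c1)))
        c3 = self.act(self.norm3(self.conv3(c2)))
        cat = ad.concat_channels([c1, c2, c3])
        return self.act(self.norm_cat(cat) + self.shortcut(x))


class ResPathUnit(Module):
    """One residual skip-processing unit: 3³ conv (normed) + 1³ projection."""

    def __init__(self, ch: int, activation: str, rng: np.random.Generator):
        self.act = activation_fn(activation)
        self.conv = Conv3d(ch, ch, 3, rng)
        self.norm = InstanceNorm3d(ch)
        self.proj = Conv3d(ch, ch, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.norm(self.conv(x)) + self.proj(x))


class ResPath(Module):
    """``n_blocks`` chained residual units applied to a skip connection."""

    def __init__(self, ch: int, n_blocks: int, activation: str,
                 rng: np.random.Generator):
        if n_blocks < 1:
            raise ConfigError("a res path needs at least one block")
        self.blocks = [ResPathUnit(ch, activation, rng) for _ in range(n_blocks)]

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class MultiResUNet3D(Module):
    """The full segmentation network; forward returns (probs, tsdf)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        act = cfg.activation
        self.pools = cfg.pool_factors()

        self.enc = []
        in_ch = cfg.in_channels
        for level in range(cfg.depth):
            block = MultiResBlock3d(in_ch, cfg.level_budget(level), act, rng)
            self.enc.append(block)
            in_ch = block.out_ch

        # deeper skips get fewer res-path blocks (level l+1 of depth → depth-1-l)
        self.res_paths = [
            ResPath(self.enc[l].out_ch, cfg.depth - 1 - l, act, rng)
            for l in range(cfg.depth - 1)
        ]

        self.ups = []
        self.dec = []
        for l in reversed(range(cfg.depth - 1)):
            below_ch = self.dec[-1].out_ch if self.dec else self.enc[-1].out_ch
            up = ConvTranspose3d(below_ch, self.enc[l].out_ch, self.pools[l], rng)
            self.ups.append(up)
            dec_block = MultiResBlock3d(self.enc[l].out_ch * 2, cfg.level_budget(l),
                                        act, rng)
            self.dec.append(dec_block)

        final_ch = self.dec[-1].out_ch
        self.class_head = Conv3d(final_ch, cfg.n_classes, 1, rng)
        self.tsdf_head = Conv3d(final_ch, cfg.n_tsdf_channels, 1, rng)

    def _check_shape(self, shape) -> None:
        d, h, w = shape
        need = [int(np.prod([f[i] for f in self.pools])) for i in range(3)]
        if d % need[0] or h % need[1] or w % need[2]:
            raise ValueError(
                f"spatial shape {shape} not divisible by pooling totals {tuple(need)}")

    def forward(self, x) -> tuple[Tensor, Tensor]:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim == 4:
            x = Tensor(x.data[None]) if not (x.requires_grad or x._parents) else x
        self._check_shape(x.shape[2:])
        skips = []
        for l, block in enumerate(self.enc):
            x = block(x)
            if l < len(self.enc) - 1:
                skips.append(x)
                x = ad.maxpool3d(x, self.pools[l])
        for i, l in enumerate(reversed(range(self.cfg.depth - 1))):
            x = self.ups[i](x)
            skip = self.res_paths[l](skips[l])
            x = self.dec[i](ad.concat_channels([x, skip]))
        probs = ad.softmax_channels(self.class_head(x))
        tsdf = ad.tanh(self.tsdf_head(x))
        return probs, tsdf

    def predict(self, channels: np.ndarray) -> np.ndarray:
        """Inference on a (3, z, y, x) array → (n_classes, z, y, x) probabilities."""
        with ad.no_grad():
            probs, _ = self.forward(Tensor(channels[None]))
        return probs.data[0]

    # ---- checkpointing --------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as f:  # exact filename, no .npz suffix appended
            np.savez(f, __config__=json.dumps(self.cfg.to_dict()), **self.state_dict())

    @classmethod
    def load(cls, path) -> "MultiResUNet3D":
        with np.load(Path(path), allow_pickle=False) as f:
            cfg = ModelConfig(**json.loads(str(f["__config__"])))
            model = cls(cfg)
            model.load_state_dict({k: f[k] for k in f.files if k != "__config__"})
        return model


def build_network(cfg: ModelConfig, seed: int = 0) -> MultiResUNet3D:
    """Construct the network from a configuration (convenience alias)."""
    return MultiResUNet3D(cfg, seed=seed)
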