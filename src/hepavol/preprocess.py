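"""Hounsfield windowing: the three-channel composite the network consumes.

Each HU window (center WC, width WW) maps intensities linearly onto
[−1, 1] with clipping: f(h) = clip((h − WC) / (WW/2), −1, 1). Three
windows are stacked into a channel axis — the full 12-bit range, an
abdominal soft-tissue window, and a narrow liver-tissue window — giving
the model both global context and contrast where liver parenchyma lives.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volume_io import CTVolume


@dataclasses.dataclass(frozen=True)
class HUWindow:
    """A CT display window: center and width in HU."""

    center: float
    width: float
    name: str = ""

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"window width must be positive, got {self.width}")


# Defaults: the full 12-bit ingest range plus standard clinical presets.
FULL_RANGE_WINDOW = HUWindow(1023.5, 4095.0, "full_range")
SOFT_TISSUE_WINDOW = HUWindow(40.0, 400.0, "abdominal_soft_tissue")
LIVER_WINDOW = HUWindow(60.0, 160.0, "liver_tissue")
DEFAULT_WINDOWS = (FULL_RANGE_WINDOW, SOFT_TISSUE_WINDOW, LIVER_WINDOW)


@dataclasses.dataclass
class MultiWindowVolume:
    """Windowed composite: (channel, z, y, x) with 3 channels in [−1, 1]."""

    channels: np.ndarray
    spacing: tuple[float, float, float]
    windows: tuple[HUWindow, HUWindow, HUWindow] = DEFAULT_WINDOWS

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4 or self.channels.shape[0] != 3:
            raise ValueError(
                f"expected (3, z, y, x) channels, got shape {self.channels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels.shape[1:]


def apply_window(v: CTVolume | np.ndarray, w: HUWindow) -> np.ndarray:
    """Map HU values through one window onto [−1, 1]."""
    if w.width <= 0:
        raise ValueError("window width must be positive")
    hu = v.voxels if isinstance(v, CTVolume) else np.asarray(v, dtype=np.float32)
    out = (hu - w.center) / (w.width / 2.0)
    return np.clip(out, -1.0, 1.0).astype(np.float32)


def make_composite(v: CTVolume, windows=DEFAULT_WINDOWS) -> MultiWindowVolume:
    """Stack the three windowed views into the network's input tensor."""
    windows = tuple(windows)
    if len(windows) != 3:
        raise ValueError(f"exactly three windows are required, got {len(windows)}")
    channels = np.stack([apply_window(v, w) for w in windows], axis=0)
    return MultiWindowVolume(channels, v.spacing, windows)
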