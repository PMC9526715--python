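"""Synthetic venous-phase abdominal CT phantoms with lobe labels and readers.

The phantom emulates the aspects of a contrast-enhanced liver CT that the
pipeline actually exercises: an anisotropically spaced HU grid (default
1.5 x 1.5 x 5 mm), a liver-like ellipsoid of enhancing parenchyma split by
an oblique plane into a larger right and smaller left compartment (the
analog of the central-hepatic-vein division), a heart-like blob superior
to the liver and a diaphragm-like sheet as confounders, and additive
Gaussian noise. Simulated readers perturb the true boundary with a smooth
random surface field and occasionally shift whole slice boundaries in the
heart-adjacent top third, where human annotations disagree most.

Everything is deterministic per seed, so fixtures are regenerated at test
time rather than stored.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .volume_io import (CTVolume, LabelVolume, HU_MIN, HU_MAX,
                        BACKGROUND, RIGHT_LOBE, LEFT_LOBE, IGNORE_LABEL)


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one phantom.

    Lengths are mm; the grid shape is (z, y, x) voxels with spacing
    (sx, sy, sz). ``right_fraction_target`` fixes the fraction of liver
    voxels assigned to the right lobe (the plane offset is solved for it).
    """

    shape: tuple[int, int, int] = (32, 96, 96)
    spacing: tuple[float, float, float] = (1.5, 1.5, 5.0)
    liver_center_mm: tuple[float, float, float] | None = None  # (z, y, x)
    liver_axes_mm: tuple[float, float, float] = (60.0, 45.0, 55.0)  # (z, y, x) semi-axes
    split_normal: tuple[float, float, float] = (0.15, 0.35, 0.92)  # (z, y, x), normalized later
    right_fraction_target: float = 0.65
    split_bend_amp_mm: float = 4.0  # sinusoidal bend of the lobe boundary
    hu_liver: float = 120.0
    hu_background: float = -50.0
    hu_heart: float = 150.0
    hu_diaphragm: float = 80.0
    heart_blob: bool = True
    diaphragm_sheet: bool = True
    noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.right_fraction_target < 1.0:
            raise ValueError("right_fraction_target must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclasses.dataclass
class ReaderSim:
    """Simulated human reader: boundary jitter plus heart-adjacent slice shifts."""

    boundary_jitter_mm: float = 1.5
    jitter_smoothness_mm: float = 12.0
    z_shift_prob: float = 0.3  # per slice in the top (heart-adjacent) third
    seed: int = 0

    def __post_init__(self):
        if self.boundary_jitter_mm < 0:
            raise ValueError("boundary jitter must be >= 0")


def _grids_mm(shape, spacing):
    nz, ny, nx = shape
    sx, sy, sz = spacing
    z = np.arange(nz, dtype=np.float64)[:, None, None] * sz
    y = np.arange(ny, dtype=np.float64)[None, :, None] * sy
    x = np.arange(nx, dtype=np.float64)[None, None, :] * sx
    return z, y, x


def _liver_geometry(spec: PhantomSpec):
    nz, ny, nx = spec.shape
    sx, sy, sz = spec.spacing
    extent = (nz * sz, ny * sy, nx * sx)
    center = spec.liver_center_mm
    if center is None:
        # liver sits slightly inferior/right of grid center, like an abdomen
        center = (0.45 * extent[0], 0.5 * extent[1], 0.45 * extent[2])
    axes = spec.liver_axes_mm
    for c, a, e in zip(center, axes, extent):
        if c - a < -1e-6 or c + a > e + 1e-6:
            raise ValueError(
                f"liver ellipsoid (center {center}, axes {axes}) does not fit grid extent {extent}")
    return center, axes


def _ellipsoid_mask(shape, spacing, center, axes):
    z, y, x = _grids_mm(shape, spacing)
    q = (((z - center[0]) / axes[0]) ** 2
         + ((y - center[1]) / axes[1]) ** 2
         + ((x - center[2]) / axes[2]) ** 2)
    return q <= 1.0


def split_signed_offset(spec: PhantomSpec, liver_mask: np.ndarray) -> np.ndarray:
    """Signed mm coordinate of each voxel along the lobe-splitting surface normal.

    Positive values lie on the right-lobe side. The plane offset is chosen
    as the empirical quantile of the coordinate over liver voxels that
    yields exactly the requested right-lobe fraction; an optional
    sinusoidal bend makes the boundary non-planar.
    """
    center, _ = _liver_geometry(spec)
    n = np.asarray(spec.split_normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    z, y, x = _grids_mm(spec.shape, spec.spacing)
    d = (z - center[0]) * n[0] + (y - center[1]) * n[1] + (x - center[2]) * n[2]
    d = np.broadcast_to(d, spec.shape).copy()
    if spec.split_bend_amp_mm:
        d = d + spec.split_bend_amp_mm * np.sin(2 * np.pi * z / max(z.max(), 1.0))
        d = np.broadcast_to(d, spec.shape).copy()
    dl = d[liver_mask]
    # right lobe = d > offset; choose offset so the right fraction hits target
    offset = np.quantile(dl, 1.0 - spec.right_fraction_target)
    return d - offset


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LabelVolume]:
    """Build one phantom: HU volume plus ground-truth lobe labels."""
    rng = np.random.default_rng(spec.seed)
    center, axes = _liver_geometry(spec)
    liver = _ellipsoid_mask(spec.shape, spec.spacing, center, axes)
    if not liver.any():
        raise ValueError("liver ellipsoid covers no voxels")

    hu = np.full(spec.shape, spec.hu_background, dtype=np.float64)
    hu[liver] = spec.hu_liver

    nz, ny, nx = spec.shape
    sx, sy, sz = spec.spacing
    if spec.heart_blob:
        # heart-like blob superior to the liver, partially in-frame
        heart_center = (min(center[0] + axes[0] * 1.05, (nz - 1) * sz),
                        center[1] - 0.15 * ny * sy, center[2])
        heart_axes = (0.6 * axes[0], 0.55 * axes[1], 0.55 * axes[2])
        heart = _ellipsoid_mask(spec.shape, spec.spacing, heart_center, heart_axes)
        hu[heart & ~liver] = spec.hu_heart
    if spec.diaphragm_sheet:
        # thin oblique sheet hugging the superior liver surface
        z, y, x = _grids_mm(spec.shape, spec.spacing)
        q = (((z - center[0]) / (axes[0] + 4.0)) ** 2
             + ((y - center[1]) / (axes[1] + 4.0)) ** 2
             + ((x - center[2]) / (axes[2] + 4.0)) ** 2)
        shell = (q <= 1.0) & ~liver & (np.broadcast_to(z, spec.shape) > center[0])
        hu[shell] = spec.hu_diaphragm

    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    hu = np.clip(hu, HU_MIN, HU_MAX)

    d = split_signed_offset(spec, liver)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[liver & (d > 0)] = RIGHT_LOBE
    labels[liver & (d <= 0)] = LEFT_LOBE

    ct = CTVolume(hu.astype(np.float32), spec.spacing)
    lv = LabelVolume(labels, spec.spacing)
    return ct, lv


def _smooth_field(shape, spacing, sigma_mm, rng):
    """Smooth unit-variance Gaussian random field on the (z, y, x) grid."""
    sx, sy, sz = spacing
    sigma_vox = (sigma_mm / sz, sigma_mm / sy, sigma_mm / sx)
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma_vox, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_reader(truth: LabelVolume, sim: ReaderSim,
                    split_d: np.ndarray | None = None) -> LabelVolume:
    """Perturb the truth the way a human annotator would.

    The liver outline and the lobe boundary are both displaced by smooth
    random fields of amplitude ``boundary_jitter_mm`` (applied to the
    signed distance of the respective surface), and in the top third of
    the volume whole slices occasionally inherit the previous slice's
    contour, mimicking slice-to-slice mismatch near the heart.
    """
    from .tsdf import signed_edt  # local import to avoid a cycle

    rng = np.random.default_rng(sim.seed)
    labels = truth.labels
    liver = labels != BACKGROUND
    out = np.zeros_like(labels)

    if sim.boundary_jitter_mm > 0 and liver.any() and not liver.all():
        sd_liver = signed_edt(liver, truth.spacing)
        jitter = sim.boundary_jitter_mm * _smooth_field(
            labels.shape, truth.spacing, sim.jitter_smoothness_mm, rng)
        liver_new = (sd_liver + jitter) > 0
    else:
        liver_new = liver.copy()
        rng.normal(size=1)  # keep the stream position stable

    right = labels == RIGHT_LOBE
    if sim.boundary_jitter_mm > 0 and right.any() and (liver & ~right).any():
        if split_d is not None:
            d = split_d
        else:
            d = signed_edt(right, truth.spacing)  # distance to the right-lobe border
        jitter2 = sim.boundary_jitter_mm * _smooth_field(
            labels.shape, truth.spacing, sim.jitter_smoothness_mm, rng)
        right_new = (d + jitter2) > 0
    else:
        right_new = right

    out[liver_new & right_new] = RIGHT_LOBE
    out[liver_new & ~right_new] = LEFT_LOBE

    nz = labels.shape[0]
    for z in range(max(1, 2 * nz // 3), nz):
        if rng.uniform() < sim.z_shift_prob:
            out[z] = out[z - 1]

    return LabelVolume(out, truth.spacing, truth.origin, truth.direction)


@dataclasses.dataclass
class PhantomCase:
    """One dataset entry: image, truth, and simulated reader annotations."""

    case_id: str
    image: CTVolume
    truth: LabelVolume
    readers: list  # list[LabelVolume]


def generate_dataset(n: int, base_seed: int = 0,
                     shape: tuple[int, int, int] = (32, 96, 96),
                     spacing: tuple[float, float, float] = (1.5, 1.5, 5.0),
                     n_readers: int = 3,
                     reader_sim: ReaderSim | None = None) -> list[PhantomCase]:
    """Generate ``n`` phantoms with varied geometry plus reader simulations.

    Semi-axes are jittered ±20%, the liver center wanders a little, and
    the right-lobe fraction is drawn from 0.60–0.70, so case volumes span
    a realistic range. Fully reproducible from ``base_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = ReaderSim() if reader_sim is None else reader_sim
    cases = []
    ss = np.random.SeedSequence(base_seed)
    for i, child in enumerate(ss.spawn(n)):
        seeds = child.generate_state(2 + n_readers)
        rng = np.random.default_rng(seeds[0])
        nz, ny, nx = shape
        sx, sy, sz = spacing
        extent = (nz * sz, ny * sy, nx * sx)
        ref_axes = (0.38 * extent[0], 0.30 * extent[1], 0.36 * extent[2])
        axes = tuple(a * rng.uniform(0.8, 1.2) for a in ref_axes)
        center = (np.clip(0.45 + rng.uniform(-0.04, 0.04), 0, 1) * extent[0],
                  np.clip(0.50 + rng.uniform(-0.04, 0.04), 0, 1) * extent[1],
                  np.clip(0.45 + rng.uniform(-0.04, 0.04), 0, 1) * extent[2])
        axes = tuple(min(a, min(c, e - c) - 1e-3) for a, c, e in zip(axes, center, extent))
        spec = PhantomSpec(shape=shape, spacing=spacing, liver_center_mm=center,
                           liver_axes_mm=axes,
                           right_fraction_target=rng.uniform(0.60, 0.70),
                           seed=int(seeds[1] % (2 ** 31)))
        ct, truth = generate_phantom(spec)
        readers = [
            simulate_reader(truth, dataclasses.replace(base, seed=int(seeds[2 + r] % (2 ** 31))))
            for r in range(n_readers)
        ]
        cases.append(PhantomCase(f"case_{i:03d}", ct, truth, readers))
    return cases
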