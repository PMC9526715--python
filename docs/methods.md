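# Methods

## Task and data model

The tool segments venous-phase abdominal CT into background (0), right
lobe (1) and left lobe (2), the lobes separated at the central-hepatic-
vein plane, and derives volumes in ml. Volumes are held as `(z, y, x)`
arrays with spacing `(sx, sy, sz)` in mm; NIfTI is the only on-disk
format, with the affine carrying spacing/origin/orientation. HU values
are clamped on ingest to the 12-bit scanner range [−1024, 3071]. A
reserved label 255 marks *ignore* voxels — positions without a reader
majority — which are excluded from every loss term and every evaluation
count.

Clinical training data for this task is private, so the package treats a
synthetic phantom cohort as its reference study condition (below).

## Preprocessing

Working resolution follows the clinical recipe: z resampled to 5 mm
slice thickness (linear for intensities, nearest-neighbour for labels),
axial slices to 256×256 with in-plane spacing rescaled to conserve
physical extent. The network input is a three-channel composite of HU
windows, each applied as `clip((h − WC)/(WW/2), −1, 1)`:

| channel | window | WC (HU) | WW (HU) |
|---|---|---|---|
| 0 | full 12-bit range | 1023.5 | 4095 |
| 1 | abdominal soft tissue | 40 | 400 |
| 2 | liver tissue | 60 | 160 |

The exact clinical window values are a design choice (standard display
presets matching the named windows); all three are configurable.

## t-SDF targets

For each lobe class the binary mask is converted to a signed Euclidean
distance in mm (`scipy.ndimage.distance_transform_edt` with anisotropic
sampling): positive inside, negative outside, *voxel-center* convention —
an inside voxel's distance is measured to the center of the nearest
outside voxel, so boundary-adjacent voxels already carry one voxel pitch.
Distances are clipped to ±25 mm and scaled to [−1, 1]. A class absent
from a volume yields an all −1 channel. The brute-force oracle used in
the tests implements the same voxel-center convention, which is why
agreement is exact (float64 throughout this path). Ignore voxels count as
background for distance purposes; their loss exclusion happens in the
loss functions.

## Network

`MultiResUNet3D` (in `hepavol.model`): encoder/decoder with MultiRes
blocks — three chained 3³ convolutions (instance norm + ReLU each), the
intermediate outputs concatenated, normalized, and added to a 1×1×1
residual projection before the activation. The per-level channel budget
`W_l = round(alpha · base_filters · 2^l)` is split over the branches as
(1/6, 1/3, 1/2)·W rounded. Skips pass through res paths (3³ conv +
instance norm + 1³ residual units), with `depth − L` units at encoder
level L so shallow skips get the most processing. Upsampling is a
transposed convolution with kernel = stride = the pooling factor. Heads:
1³ conv + softmax (3 classes) and 1³ conv + tanh (2 t-SDF channels, the
tanh matching the target range).

Pooling is 2×2×2, but the z axis is only pooled while the configured
crop's z extent is ≥ 8 slices (then 1×2×2), so thin axial crops survive
deep networks. Default full-scale configuration: depth 5, base_filters
32, alpha 1.67 (the original MultiRes recipe carried to 3D); the desk
profile uses depth 2, base_filters 8.

Implementation note: no GPU tensor library is part of the dependency set;
the network runs on `hepavol.nn`, a small reverse-mode autodiff engine
over NumPy (im2col + BLAS matmul convolutions, einsum transposed
convolutions, blockwise max pooling, instance norm). Gradients of every
op are finite-difference-checked in the test suite.

## Loss

`L = w_ce·CE + w_dice·GDL + w_l1·L1`, defaults (1, 1, 1) (the component
weighting is not pinned by the recipe; it is configurable). CE is the
mean −log p(true class) over non-ignore voxels (ε = 1e-7 inside the
log). GDL sums over all classes including background with class weights
`w_c = 1/(Σ_v g_cv)²` and ε = 1e-6 guards in numerator and denominator,
so absent classes contribute negligibly rather than dividing by zero.
The t-SDF L1 term is the mean absolute error over both channels at
non-ignore voxels; it is deliberately not masked by class, since the
target is defined everywhere.

## Training

AdamW with constant lr 1e-4 and decoupled weight decay 1e-4 — the decay
multiplies parameters directly each step, outside the adaptive moments
and independent of the learning rate. Batch size 1 (instance norm has no
batch dependence), 40,000 steps ≙ 500 epochs at 80 steps/epoch; the loop
is step-based so datasets of any size keep the same step semantics.
Augmentation per crop, in fixed order: axial rotation U(−10°, 10°) →
independent per-axis scaling U(0.8, 1.2) → random 32×128×128 crop.
Labels use nearest-neighbour; image and t-SDF are interpolated linearly,
the t-SDF being transformed rather than recomputed (scale ≤ 1.2 bounds
the distance distortion at 20%, accepted as augmentation noise).
Out-of-field fills: image −1, labels 0, t-SDF −1.

Every eval interval (800 steps ≙ 10 epochs) the fold's validation cases
are segmented with the sliding-window predictor and the mean over
foreground classes of the Dice of the argmax labels is recorded; the
checkpoint is overwritten only on improvement, making the stored
validation Dice monotone. Cross-validation uses a deterministic shuffled
k-fold partition (val sizes differ by ≤ 1); all randomness — fold
shuffling, data order, augmentation, initialization — derives from one
seed via `SeedSequence`, so runs reproduce exactly.

## Inference

Sliding windows of `crop_z` slices at 75% overlap (stride `crop_z/4`),
the final window snapped to the last slice; volumes thinner than one
crop are padded with −1 and un-padded afterwards. Per-slice aggregation
weights: plateau of 1.0 on the central half, linear ramp
`(i+1)/(taper+1)` over the tapers — "nearly zero" but never zero, so
every slice retains weight even when covered by a single window (a
cosine ramp is available). Aggregation divides by the summed weights and
renormalizes per voxel, so probabilities sum to 1 and a constant field
passes through unchanged. Fold ensembling averages probability volumes
(late fusion); ties in the final argmax go to the lowest class id, i.e.
background wins.

## Evaluation protocol

Per structure (liver = union of the lobes, right lobe, left lobe):
Dice/precision/recall by voxel counting with reference-side ignore
voxels excluded (empty-vs-empty counts as 1.0 by convention); volume =
count × voxel volume / 1000 (ml); VD = V_pred − V_ref signed, positive =
over-prediction; RVD = 100·VD/V_ref. Signed rather than absolute VD/RVD
is reported (absolute means are derivable from the per-case table).
Across cases: Bland–Altman bias with 1.96·sd limits of agreement (sample
sd, n−1) and OLS regression of predicted on reference volumes
(statsmodels; slope, intercept, R², F-test), plus Shapiro–Wilk normality
(scipy). The reader/tool agreement matrix compares the raw annotations
of the three readers and the prediction pairwise — Dice mean ± sd in the
upper triangle, volume R² in the lower — with no ignore masking between
raw readers; only metrics against the majority-vote SoR use the ignore
label. Majority voting requires a strict majority (> n/2 readers).

## Phantom cohort (the synthetic study conditions)

Each phantom emulates the features of venous-phase liver CT this
pipeline actually consumes: grid 1.5×1.5×5 mm; background −50 HU; liver
= an ellipsoid at 120 HU split by an oblique plane (normal roughly
sagittal, slight sinusoidal bend) into a right compartment holding 65%
of the volume (per-case 60–70%); a heart-like blob (150 HU) superior to
the liver; a thin diaphragm-like shell (80 HU) hugging its superior
surface; Gaussian noise sd 15 HU. The plane offset is solved as the
empirical quantile of the signed plane coordinate over liver voxels, so
the right fraction is hit essentially exactly. Simulated readers displace
the liver outline and lobe boundary by smooth Gaussian random fields of
amplitude 1.5 mm (correlation length 12 mm) and, with probability 0.3
per slice in the superior third, copy the previous slice's contour —
mimicking the slice-to-slice mismatch human readers show near the heart.
Reader-vs-truth Dice lands around 0.95–0.99.

What the phantoms do *not* model: vasculature and ducts, neighbouring
organs of similar HU (stomach, spleen, kidney), breathing/deformation,
scanner-specific noise texture, pathology. Passing tests on phantoms
therefore demonstrates that the machinery — preprocessing, targets,
optimization, stitching, volumetry — is correct and trainable, not that
clinical accuracy transfers.

## Desk-scale profile and problem sizes

All tests and the acceptance run use a scaled profile chosen once:
phantoms of 24×64×64 voxels (≈200 ml livers), training crops 8×64×64,
sliding-window crop_z 8 (plateau 4, taper 2 — the same 1/2 and 1/4
proportions as the 32/16/8 full-scale profile), model depth 2 with 8
base filters (~17k parameters), 2 folds × 240 steps, lr 1e-3. The raised
learning rate reflects the shorter schedule (a few hundred steps versus
40,000) on easier data; the single-phantom capacity check in the tests
pushes this further to 5e-3, which a one-case memorization task
tolerates. On one CPU a fold trains in ~2 minutes and a full
cohort-to-report run takes ~5 minutes, with held-out whole-liver Dice
typically 0.92–0.93 and OLS slope ≈ 1 — qualitatively reproducing the
over-prediction-with-near-identity-slope pattern reported for the
clinical tool, at phantom scale.

## Numerical choices and edge cases

- Probabilities renormalized after aggregation/fusion; argmax ties →
  lowest class id.
- `signed_edt` raises on all-inside/all-outside masks; `compute_tsdf`
  maps absent classes to −1 (and all-covering classes to +1) instead.
- Losses raise `LossUndefinedError` when every voxel is ignored;
  training aborts on non-finite loss with a diagnostic.
- Resampling short-circuits identity targets so no interpolation noise
  is introduced; label resampling is nearest-neighbour everywhere (label
  closure: no new values can appear).
- OLS R² is defined as 0 for a constant prediction (statsmodels returns
  −inf); Shapiro–Wilk rejects constant samples and n outside [3, 5000].
- Checkpoints store weights plus the model configuration in one `.ckpt`
  (NumPy archive) file; loading reconstructs the network exactly.

## Known limitations

Paper-scale training (depth 5 on 32×256×256 windows, 40k steps) is far
outside one-CPU budgets; the NumPy engine is sized for the desk profile.
Lobe-split accuracy on phantoms is limited by the small receptive field
of the depth-2 profile — the split is positional, not textural — which
is visible as lower left-lobe Dice. DICOM ingestion, surface-distance
metrics (Hausdorff/ASSD), test-time augmentation and connected-component
post-processing are out of scope.
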