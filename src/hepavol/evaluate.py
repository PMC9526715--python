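"""Volumetry and agreement analytics.

Overlap metrics (Sørensen-Dice, precision, recall) are voxel-count based
and exclude reference voxels carrying the ignore label. Volumes are voxel
counts times voxel volume, reported in ml. Volume agreement across cases
uses the volume difference VD = pred − ref (ml, signed: positive when the
tool over-predicts), the relative volume difference RVD = 100·VD/ref (%),
Bland–Altman bias ± 1.96·sd limits of agreement, and ordinary least
squares regression of predicted on reference volumes (slope, intercept,
R², F-test). A majority-vote standard of reference is derived from
multiple readers, with non-majority voxels set to the ignore label.

The "liver" structure is the union of the two lobe classes; per-structure
helpers accept either a single class id or the LIVER sentinel.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .volume_io import LabelVolume, RIGHT_LOBE, LEFT_LOBE, IGNORE_LABEL

#: pseudo class id meaning "union of right and left lobe"
LIVER = -1
STRUCTURES = {"liver": LIVER, "right_lobe": RIGHT_LOBE, "left_lobe": LEFT_LOBE}


class AlignmentError(ValueError):
    """Volumes being compared do not share a voxel grid."""


def _labels(lv) -> np.ndarray:
    return lv.labels if isinstance(lv, LabelVolume) else np.asarray(lv)


def _class_mask(labels: np.ndarray, class_id: int) -> np.ndarray:
    if class_id == LIVER:
        return (labels == RIGHT_LOBE) | (labels == LEFT_LOBE)
    return labels == class_id


def overlap_metrics(pred, ref, class_id: int,
                    ignore_value: int = IGNORE_LABEL) -> tuple[float, float, float]:
    """(dice, precision, recall) for one structure, ignore voxels excluded.

    Only voxels whose *reference* label is the ignore value are excluded
    from the TP/FP/FN counting. Empty-vs-empty compares as perfect (1.0).
    """
    p, r = _labels(pred), _labels(ref)
    if p.shape != r.shape:
        raise AlignmentError(f"shape mismatch {p.shape} vs {r.shape}")
    valid = r != ignore_value
    pm = _class_mask(p, class_id) & valid
    rm = _class_mask(r, class_id) & valid
    tp = int(np.count_nonzero(pm & rm))
    fp = int(np.count_nonzero(pm & ~rm))
    fn = int(np.count_nonzero(~pm & rm))
    if tp + fp + fn == 0:
        return 1.0, 1.0, 1.0
    dice = 2.0 * tp / (2.0 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    return dice, precision, recall


def volume_ml(lv, class_id: int, spacing=None) -> float:
    """Structure volume in ml: voxel count × voxel volume (mm³) / 1000."""
    labels = _labels(lv)
    if spacing is None:
        spacing = lv.spacing
    sx, sy, sz = spacing
    n = int(np.count_nonzero(_class_mask(labels, class_id)))
    return n * sx * sy * sz / 1000.0


def vd_rvd(pred_ml: float, ref_ml: float) -> tuple[float, float]:
    """Signed volume difference (ml) and relative volume difference (%)."""
    vd = pred_ml - ref_ml
    if ref_ml == 0:
        raise ZeroDivisionError("RVD undefined for a zero reference volume")
    return vd, 100.0 * vd / ref_ml


def majority_vote_sor(readers, ignore_value: int = IGNORE_LABEL) -> LabelVolume:
    """Majority-vote standard of reference over ≥ 2 reader label maps.

    A voxel keeps the label chosen by a strict majority of readers
    (> n/2 votes); voxels without such a majority get the ignore label.
    """
    readers = list(readers)
    if len(readers) < 2:
        raise ValueError("at least two readers are required")
    arrs = [_labels(r) for r in readers]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise AlignmentError("reader label maps are not aligned")
    stack = np.stack(arrs)
    n = len(arrs)
    values = np.unique(stack)
    counts = np.stack([(stack == v).sum(axis=0) for v in values])
    best = counts.argmax(axis=0)
    best_count = np.take_along_axis(counts, best[None], axis=0)[0]
    out = values[best].astype(np.uint8)
    out[best_count * 2 <= n] = ignore_value
    first = readers[0]
    if isinstance(first, LabelVolume):
        return LabelVolume(out, first.spacing, first.origin, first.direction,
                           ignore_value=ignore_value)
    return LabelVolume(out, (1.0, 1.0, 1.0), ignore_value=ignore_value)


def bland_altman(pred_mls, ref_mls) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high): mean difference ± 1.96 sample sd."""
    pred = np.asarray(pred_mls, dtype=float)
    ref = np.asarray(ref_mls, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("paired 1D lists of equal length are required")
    if pred.size < 2:
        raise ValueError("at least two paired measurements are required")
    d = pred - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def ols_fit(pred_mls, ref_mls) -> tuple[float, float, float, float]:
    """OLS of predicted on reference volumes: (slope, intercept, R², F p-value)."""
    pred = np.asarray(pred_mls, dtype=float)
    ref = np.asarray(ref_mls, dtype=float)
    if pred.size != ref.size or pred.size < 3:
        raise ValueError("at least three paired measurements are required")
    if np.ptp(ref) == 0:
        raise ValueError("reference volumes have zero variance")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(pred, sm.add_constant(ref)).fit()
        intercept, slope = res.params
        r2 = 0.0 if np.ptp(pred) == 0 else float(res.rsquared)  # constant pred: no variance explained
        return float(slope), float(intercept), r2, float(res.f_pvalue)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk normality test (delegates to scipy.stats.shapiro)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


@dataclasses.dataclass
class AgreementMatrix:
    """Triangular inter-rater agreement layout.

    ``dice_mean``/``dice_sd`` fill the upper triangle (pairwise Dice across
    cases, mean ± sd); ``r2`` fills the lower triangle (OLS R² of the
    paired per-case volumes). The diagonal is NaN.
    """

    entities: list
    dice_mean: np.ndarray
    dice_sd: np.ndarray
    r2: np.ndarray

    def as_dict(self) -> dict:
        e = self.entities
        out = {"entities": list(e), "dice": {}, "r2": {}}
        for i in range(len(e)):
            for j in range(i + 1, len(e)):
                key = f"{e[i]}-{e[j]}"
                out["dice"][key] = {"mean": float(self.dice_mean[i, j]),
                                    "sd": float(self.dice_sd[i, j])}
                out["r2"][key] = float(self.r2[j, i])
        return out


def agreement_matrix(reader_sets, ai_preds, class_id: int,
                     entity_names=("R1", "R2", "R3", "AI")) -> AgreementMatrix:
    """Pairwise agreement of readers and tool across cases for one structure.

    ``reader_sets`` is one list of reader label maps per case; ``ai_preds``
    the tool's label map per case. Reader-vs-reader (and reader-vs-AI)
    comparisons use the raw annotations without any ignore masking.
    """
    n_cases = len(ai_preds)
    if n_cases < 2:
        raise ValueError("at least two cases are needed for volume R²")
    per_case_entities = [list(rs) + [ai] for rs, ai in zip(reader_sets, ai_preds)]
    m = len(per_case_entities[0])
    if m != len(entity_names):
        raise ValueError(f"expected {len(entity_names)} entities per case, got {m}")

    dice_mean = np.full((m, m), np.nan)
    dice_sd = np.full((m, m), np.nan)
    r2 = np.full((m, m), np.nan)
    vols = np.array([[volume_ml(ent, class_id) for ent in ents]
                     for ents in per_case_entities])  # (case, entity)
    for i in range(m):
        for j in range(i + 1, m):
            dices = [overlap_metrics(ents[i], ents[j], class_id)[0]
                     for ents in per_case_entities]
            dice_mean[i, j] = float(np.mean(dices))
            dice_sd[i, j] = float(np.std(dices, ddof=1)) if len(dices) > 1 else 0.0
            r2[j, i] = _volume_r2(vols[:, j], vols[:, i])
    return AgreementMatrix(list(entity_names), dice_mean, dice_sd, r2)


def _volume_r2(pred, ref) -> float:
    if np.ptp(ref) == 0:
        return float("nan")
    return ols_fit(pred, ref)[2] if pred.size >= 3 else _r2_two_point(pred, ref)


def _r2_two_point(pred, ref) -> float:
    # with two cases a line fits exactly unless degenerate
    return 1.0 if np.ptp(ref) != 0 else float("nan")


def evaluate_cases(preds, refs, structures=STRUCTURES,
                   ignore_value: int = IGNORE_LABEL) -> dict:
    """Full volumetry report: per-case metrics plus aggregate agreement.

    ``preds``/``refs`` are parallel lists of label maps (refs may carry the
    ignore label, e.g. a majority-vote SoR). Returns a JSON-serializable
    dict with per-case Dice/precision/recall/VD/RVD and, per structure,
    aggregate means, Bland–Altman bias/LoA and OLS volume regression
    (when enough cases are available).
    """
    if len(preds) != len(refs) or not preds:
        raise ValueError("preds and refs must be equal-length, non-empty lists")
    report = {"n_cases": len(preds), "per_case": [], "aggregate": {}}
    vols: dict = {name: {"pred": [], "ref": []} for name in structures}
    for k, (p, r) in enumerate(zip(preds, refs)):
        entry = {"case": k, "structures": {}}
        for name, cid in structures.items():
            dice, prec, rec = overlap_metrics(p, r, cid, ignore_value)
            pv, rv = volume_ml(p, cid), volume_ml(r, cid)
            vd = pv - rv
            rvd = 100.0 * vd / rv if rv > 0 else float("nan")
            entry["structures"][name] = {
                "dice": dice, "precision": prec, "recall": rec,
                "pred_ml": pv, "ref_ml": rv, "vd_ml": vd, "rvd_pct": rvd,
            }
            vols[name]["pred"].append(pv)
            vols[name]["ref"].append(rv)
        report["per_case"].append(entry)
    for name in structures:
        pred = np.array(vols[name]["pred"])
        ref = np.array(vols[name]["ref"])
        cases = [c["structures"][name] for c in report["per_case"]]
        agg = {
            "dice_mean": float(np.mean([c["dice"] for c in cases])),
            "dice_sd": float(np.std([c["dice"] for c in cases], ddof=1)) if len(cases) > 1 else 0.0,
            "precision_mean": float(np.mean([c["precision"] for c in cases])),
            "recall_mean": float(np.mean([c["recall"] for c in cases])),
            "vd_ml_mean": float(np.mean(pred - ref)),
            "rvd_pct_mean": float(np.nanmean([c["rvd_pct"] for c in cases])),
            "abs_rvd_pct_mean": float(np.nanmean([abs(c["rvd_pct"]) for c in cases])),
        }
        if len(cases) >= 2:
            bias, lo, hi = bland_altman(pred, ref)
            agg["bland_altman"] = {"bias_ml": bias, "loa_low_ml": lo, "loa_high_ml": hi}
        if len(cases) >= 3 and np.ptp(ref) > 0:
            slope, intercept, r2_, fp = ols_fit(pred, ref)
            agg["ols"] = {"slope": slope, "intercept_ml": intercept,
                          "r2": r2_, "f_pvalue": fp}
        report["aggregate"][name] = agg
    return report
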