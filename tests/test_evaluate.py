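import itertools

import numpy as np
import pytest

from hepavol import evaluate as ev
from hepavol.volume_io import LabelVolume


def _lv(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(np.asarray(arr, np.uint8), spacing)


# ---- overlap metrics ----------------------------------------------------------

def test_overlap_hand_counts():
    ref = np.zeros((1, 1, 10), np.uint8)
    ref[0, 0, :4] = 1
    pred = np.zeros((1, 1, 10), np.uint8)
    pred[0, 0, 1:7] = 1  # |pred|=6, |ref|=4, overlap 3
    dice, prec, rec = ev.overlap_metrics(_lv(pred), _lv(ref), 1)
    assert (dice, prec, rec) == pytest.approx((0.6, 0.5, 0.75))


def test_overlap_identity_disjoint_empty():
    a = np.zeros((2, 2, 2), np.uint8)
    a[0] = 1
    assert ev.overlap_metrics(_lv(a), _lv(a), 1) == (1.0, 1.0, 1.0)
    b = np.zeros_like(a)
    b[1] = 1
    assert ev.overlap_metrics(_lv(a), _lv(b), 1) == (0.0, 0.0, 0.0)
    empty = np.zeros_like(a)
    assert ev.overlap_metrics(_lv(empty), _lv(empty), 1) == (1.0, 1.0, 1.0)


def test_overlap_brute_force_with_ignore(rng):
    """Dice/precision/recall match per-voxel counting on random pairs."""
    for _ in range(100):
        pred = rng.integers(0, 3, size=(5, 5, 5)).astype(np.uint8)
        ref = rng.integers(0, 3, size=(5, 5, 5)).astype(np.uint8)
        ref[rng.uniform(size=ref.shape) < 0.2] = 255
        cid = int(rng.integers(1, 3))
        tp = fp = fn = 0
        for idx in np.ndindex(5, 5, 5):
            if ref[idx] == 255:
                continue
            p, r = pred[idx] == cid, ref[idx] == cid
            tp += p and r
            fp += p and not r
            fn += r and not p
        want = (2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0,
                tp / (tp + fp) if (tp + fp) else (1.0 if tp + fn == 0 else 0.0),
                tp / (tp + fn) if (tp + fn) else (1.0 if tp + fp == 0 else 0.0))
        got = ev.overlap_metrics(_lv(pred), _lv(ref), cid)
        if tp + fp + fn == 0:
            assert got == (1.0, 1.0, 1.0)
        else:
            assert got == pytest.approx(want)


def test_metric_symmetry(rng):
    a = rng.integers(0, 3, size=(4, 4, 4)).astype(np.uint8)
    b = rng.integers(0, 3, size=(4, 4, 4)).astype(np.uint8)
    da = ev.overlap_metrics(_lv(a), _lv(b), 1)
    db = ev.overlap_metrics(_lv(b), _lv(a), 1)
    assert da[0] == pytest.approx(db[0])          # Dice symmetric
    assert da[1] == pytest.approx(db[2])          # precision(a,b) == recall(b,a)


def test_ignore_neutrality_in_reference(rng):
    pred = rng.integers(0, 3, size=(4, 4, 4)).astype(np.uint8)
    ref = rng.integers(0, 3, size=(4, 4, 4)).astype(np.uint8)
    base = ev.overlap_metrics(_lv(pred), _lv(ref), 1)
    ref2 = ref.copy()
    ref2[0, 0, :2] = 255
    pred2 = pred.copy()
    pred2[0, 0, :2] = (pred[0, 0, :2] + 1) % 3  # prediction there is irrelevant
    got = ev.overlap_metrics(_lv(pred2), _lv(ref2), 1)
    want = ev.overlap_metrics(_lv(pred), _lv(ref2), 1)
    assert got == want
    assert base != want or (ref[0, 0, :2] != 1).all()


# ---- volumes ------------------------------------------------------------------

def test_volume_ml_values():
    labels = np.zeros((10, 10, 10), np.uint8)
    labels.flat[:1000] = 1
    lv = _lv(labels, (1.5, 1.5, 5.0))
    assert ev.volume_ml(lv, 1) == pytest.approx(11.25)  # 1000 × 11.25 mm³
    assert ev.volume_ml(lv, 2) == 0.0
    assert ev.volume_ml(lv, ev.LIVER) == pytest.approx(
        ev.volume_ml(lv, 1) + ev.volume_ml(lv, 2))


def test_vd_rvd_sign_convention():
    assert ev.vd_rvd(1032.0, 1000.0) == pytest.approx((32.0, 3.2))
    assert ev.vd_rvd(900.0, 1000.0) == pytest.approx((-100.0, -10.0))
    assert ev.vd_rvd(5.0, 5.0) == (0.0, 0.0)
    with pytest.raises(ZeroDivisionError):
        ev.vd_rvd(1.0, 0.0)


# ---- majority vote SoR --------------------------------------------------------

def test_sor_enumeration_oracle():
    """All 27 three-reader label triples against the voting truth table."""
    triples = list(itertools.product([0, 1, 2], repeat=3))
    arrs = [np.array([t[r] for t in triples], np.uint8).reshape(3, 3, 3)
            for r in range(3)]
    sor = ev.majority_vote_sor([_lv(a) for a in arrs]).labels.ravel()
    for k, t in enumerate(triples):
        counts = {v: t.count(v) for v in set(t)}
        label, n = max(counts.items(), key=lambda kv: kv[1])
        want = label if n >= 2 else 255
        assert sor[k] == want, f"votes {t}"


def test_sor_examples_and_validation():
    r = [_lv(np.full((1, 1, 1), v, np.uint8)) for v in (1, 1, 2)]
    assert ev.majority_vote_sor(r).labels[0, 0, 0] == 1
    r = [_lv(np.full((1, 1, 1), v, np.uint8)) for v in (0, 1, 2)]
    assert ev.majority_vote_sor(r).labels[0, 0, 0] == 255
    with pytest.raises(ValueError):
        ev.majority_vote_sor([r[0]])


# ---- agreement statistics -----------------------------------------------------

def test_bland_altman_cases():
    assert ev.bland_altman([1, 2, 3], [1, 2, 3]) == pytest.approx((0, 0, 0))
    bias, lo, hi = ev.bland_altman([2, -2], [0, 0])
    sd = np.std([2, -2], ddof=1)  # 2*sqrt(2)
    assert (bias, lo, hi) == pytest.approx((0.0, -1.96 * sd, 1.96 * sd))
    assert ev.bland_altman([6, 7, 8], [1, 2, 3]) == pytest.approx((5, 5, 5))
    with pytest.raises(ValueError):
        ev.bland_altman([1], [1])


def test_ols_fit_cases():
    ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    slope, intercept, r2, _ = ev.ols_fit(2 * ref + 1, ref)
    assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    slope, intercept, r2, _ = ev.ols_fit(np.full(5, 3.0), ref)
    assert (slope, r2) == pytest.approx((0.0, 0.0), abs=1e-12)

    # hand-solved normal equations on a 5-point toy set
    pred = np.array([2.1, 2.9, 4.2, 5.1, 5.7])
    sxx = np.sum((ref - ref.mean()) ** 2)
    sxy = np.sum((ref - ref.mean()) * (pred - pred.mean()))
    b = sxy / sxx
    a = pred.mean() - b * ref.mean()
    slope, intercept, r2, fp = ev.ols_fit(pred, ref)
    assert slope == pytest.approx(b)
    assert intercept == pytest.approx(a)
    resid = pred - (a + b * ref)
    assert r2 == pytest.approx(1 - np.sum(resid ** 2) / np.sum((pred - pred.mean()) ** 2))
    assert fp < 0.01
    with pytest.raises(ValueError):
        ev.ols_fit([1, 2, 3], [2, 2, 2])


def test_shapiro_wilk_delegation(rng):
    w, p = ev.shapiro_wilk([-1.0, 0.0, 1.0])
    assert 0 < w <= 1 and p > 0.05
    skewed = np.exp(rng.normal(size=50)) ** 3
    _, p = ev.shapiro_wilk(skewed)
    assert p < 0.05
    with pytest.raises(ValueError):
        ev.shapiro_wilk([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        ev.shapiro_wilk([1.0, 2.0])


# ---- agreement matrix ---------------------------------------------------------

def _toy_cases(rng, n_cases=3):
    readers_per_case, ai = [], []
    for _ in range(n_cases):
        base = np.zeros((4, 6, 6), np.uint8)
        k = int(rng.integers(2, 5))
        base[:, 1:1 + k, 1:5] = 1
        base[:, 1 + k:5, 1:5] = 2
        rs = []
        for _ in range(3):
            r = base.copy()
            flip = rng.uniform(size=r.shape) < 0.05
            r[flip] = rng.integers(0, 3, size=int(flip.sum()))
            rs.append(_lv(r))
        readers_per_case.append(rs)
        a = base.copy()
        flip = rng.uniform(size=a.shape) < 0.05
        a[flip] = rng.integers(0, 3, size=int(flip.sum()))
        ai.append(_lv(a))
    return readers_per_case, ai


def test_agreement_matrix_identical_entities():
    base = np.zeros((2, 4, 4), np.uint8)
    base[:, :2] = 1
    cases = [_lv(base), _lv((base + 0) * 1)]
    readers = [[c, c, c] for c in cases]
    m = ev.agreement_matrix(readers, cases, 1)
    upper = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    assert len(upper) == 6
    for i, j in upper:
        assert m.dice_mean[i, j] == pytest.approx(1.0)
        assert m.dice_sd[i, j] == pytest.approx(0.0)


def test_agreement_matrix_matches_pairwise_metrics(rng):
    readers, ai = _toy_cases(rng)
    m = ev.agreement_matrix(readers, ai, 1)
    # spot-check R1 vs R2 and R3 vs AI against direct computation
    d12 = [ev.overlap_metrics(rs[0], rs[1], 1)[0] for rs in readers]
    assert m.dice_mean[0, 1] == pytest.approx(np.mean(d12))
    assert m.dice_sd[0, 1] == pytest.approx(np.std(d12, ddof=1))
    v3 = [ev.volume_ml(rs[2], 1) for rs in readers]
    vai = [ev.volume_ml(a, 1) for a in ai]
    assert m.r2[3, 2] == pytest.approx(ev.ols_fit(vai, v3)[2])
    d = m.as_dict()
    assert set(d["dice"]) == {"R1-R2", "R1-R3", "R1-AI", "R2-R3", "R2-AI", "R3-AI"}


def test_evaluate_cases_report(rng):
    readers, ai = _toy_cases(rng)
    sors = [ev.majority_vote_sor(rs) for rs in readers]
    rep = ev.evaluate_cases(ai, sors)
    assert rep["n_cases"] == 3
    liver = rep["aggregate"]["liver"]
    assert 0.5 < liver["dice_mean"] <= 1.0
    assert "bland_altman" in liver and "ols" in liver
    case0 = rep["per_case"][0]["structures"]["liver"]
    d, p, r = ev.overlap_metrics(ai[0], sors[0], ev.LIVER)
    assert case0["dice"] == pytest.approx(d)
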