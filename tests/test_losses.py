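import numpy as np
import pytest

from hepavol import losses
from hepavol.losses import LossWeights


def _one_hot(labels, n_classes=3):
    return np.stack([(labels == c).astype(np.float32) for c in range(n_classes)])


def test_cross_entropy_perfect_and_uniform():
    labels = np.array([[[0, 1], [2, 1]]], np.uint8).reshape(1, 2, 2)
    probs = _one_hot(labels.reshape(1, 2, 2))
    assert losses.masked_cross_entropy(probs, labels) == pytest.approx(0.0, abs=1e-5)

    uniform = np.full((3, 1, 2, 2), 1 / 3, np.float32)
    assert losses.masked_cross_entropy(uniform, labels) == pytest.approx(np.log(3), abs=1e-4)


def test_cross_entropy_ignore_removes_exactly_one_term():
    # 2-voxel hand example: -log(0.5) and -log(0.25); ignoring the second
    # leaves only the first term
    probs = np.zeros((3, 1, 1, 2), np.float32)
    probs[:, 0, 0, 0] = [0.5, 0.3, 0.2]
    probs[:, 0, 0, 1] = [0.25, 0.5, 0.25]
    labels = np.array([0, 0], np.uint8).reshape(1, 1, 2)
    both = losses.masked_cross_entropy(probs, labels)
    assert both == pytest.approx((-np.log(0.5) - np.log(0.25)) / 2, abs=1e-4)
    labels_ign = np.array([0, 255], np.uint8).reshape(1, 1, 2)
    one = losses.masked_cross_entropy(probs, labels_ign)
    assert one == pytest.approx(-np.log(0.5), abs=1e-4)


def test_cross_entropy_all_ignored_raises():
    probs = np.full((3, 1, 1, 1), 1 / 3, np.float32)
    with pytest.raises(losses.LossUndefinedError):
        losses.masked_cross_entropy(probs, np.full((1, 1, 1), 255, np.uint8))


def test_generalized_dice_extremes():
    labels = np.array([[0, 1], [2, 2]], np.uint8).reshape(1, 2, 2)
    perfect = _one_hot(labels.reshape(1, 2, 2))
    assert losses.generalized_soft_dice(perfect, labels) == pytest.approx(0.0, abs=1e-4)

    disjoint = _one_hot((labels.reshape(1, 2, 2) + 1) % 3)
    assert losses.generalized_soft_dice(disjoint, labels) == pytest.approx(1.0, abs=1e-4)


def test_generalized_dice_two_voxel_hand_case():
    # two voxels, two classes: g = (A, B), p = ((0.8, 0.2), (0.4, 0.6))
    # w_A = w_B = 1; num = 0.8 + 0.6 = 1.4; den = 2.2 + 1.8 = 4.0
    # GDL = 1 - 2*1.4/4.0 = 0.3
    probs = np.zeros((2, 1, 1, 2), np.float32)
    probs[:, 0, 0, 0] = [0.8, 0.2]
    probs[:, 0, 0, 1] = [0.4, 0.6]
    labels = np.array([0, 1], np.uint8).reshape(1, 1, 2)
    assert losses.generalized_soft_dice(probs, labels) == pytest.approx(0.3, abs=1e-4)


def test_l1_tsdf_brute_force(rng):
    pred = rng.uniform(-1, 1, size=(2, 3, 3, 3)).astype(np.float32)
    target = rng.uniform(-1, 1, size=(2, 3, 3, 3)).astype(np.float32)
    labels = rng.integers(0, 3, size=(3, 3, 3)).astype(np.uint8)
    got = losses.l1_tsdf(pred, target, labels)
    assert got == pytest.approx(np.abs(pred - target).mean(), abs=1e-6)

    labels[0, 0, 0] = 255
    valid = labels != 255
    want = np.abs(pred - target)[:, valid].mean()
    assert losses.l1_tsdf(pred, target, labels) == pytest.approx(want, abs=1e-6)


def test_ignore_mask_neutrality(rng):
    """Changing predictions only at ignore voxels changes no loss term."""
    labels = rng.integers(0, 3, size=(4, 4, 4)).astype(np.uint8)
    labels[rng.uniform(size=labels.shape) < 0.3] = 255
    assert (labels == 255).any() and (labels != 255).any()
    logits = rng.normal(size=(3, 4, 4, 4))
    probs = np.exp(logits) / np.exp(logits).sum(0)
    tsdf_pred = rng.uniform(-1, 1, size=(2, 4, 4, 4)).astype(np.float32)
    tsdf_tgt = rng.uniform(-1, 1, size=(2, 4, 4, 4)).astype(np.float32)

    base = (losses.masked_cross_entropy(probs, labels),
            losses.generalized_soft_dice(probs, labels),
            losses.l1_tsdf(tsdf_pred, tsdf_tgt, labels))
    for _ in range(5):
        probs2, tp2 = probs.copy(), tsdf_pred.copy()
        ign = labels == 255
        noise = rng.normal(size=(3, int(ign.sum())))
        probs2[:, ign] = np.exp(noise) / np.exp(noise).sum(0)
        tp2[:, ign] = rng.uniform(-1, 1, size=(2, int(ign.sum())))
        after = (losses.masked_cross_entropy(probs2, labels),
                 losses.generalized_soft_dice(probs2, labels),
                 losses.l1_tsdf(tp2, tsdf_tgt, labels))
        np.testing.assert_allclose(after, base, rtol=1e-5, atol=1e-6)


def test_combined_loss_composition(rng):
    labels = rng.integers(0, 3, size=(4, 4, 4)).astype(np.uint8)
    logits = rng.normal(size=(3, 4, 4, 4))
    probs = (np.exp(logits) / np.exp(logits).sum(0)).astype(np.float32)
    tp = rng.uniform(-1, 1, size=(2, 4, 4, 4)).astype(np.float32)
    tt = rng.uniform(-1, 1, size=(2, 4, 4, 4)).astype(np.float32)

    ce = losses.masked_cross_entropy(probs, labels)
    gd = losses.generalized_soft_dice(probs, labels)
    l1 = losses.l1_tsdf(tp, tt, labels)
    assert losses.combined_loss(probs, tp, labels, tt, LossWeights(1, 0, 0)) == pytest.approx(ce, rel=1e-5)
    assert losses.combined_loss(probs, tp, labels, tt, LossWeights(0, 0, 1)) == pytest.approx(l1, rel=1e-5)
    total = losses.combined_loss(probs, tp, labels, tt, LossWeights(1, 1, 1))
    assert total == pytest.approx(ce + gd + l1, rel=1e-5)


def test_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(-1, 1, 1)
    with pytest.raises(ValueError):
        LossWeights(0, 0, 0)
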