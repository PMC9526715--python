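import numpy as np
import pytest

from hepavol import infer
from hepavol.preprocess import MultiWindowVolume


def _vol(nz, ny=16, nx=16, seed=0):
    rng = np.random.default_rng(seed)
    return MultiWindowVolume(rng.uniform(-1, 1, size=(3, nz, ny, nx)).astype(np.float32),
                             (1.5, 1.5, 5.0))


class ConstantModel:
    """Stub emitting one fixed class distribution at every voxel."""

    def __init__(self, dist=(0.6, 0.3, 0.1)):
        self.dist = np.asarray(dist, np.float64)

    def __call__(self, crop):
        shape = crop.shape[1:]
        return np.broadcast_to(self.dist[:, None, None, None],
                               (3,) + shape).copy()


def test_weight_profile_paper_geometry():
    p = infer.make_weight_profile(32, 16, 8)
    assert len(p.weights) == 32
    np.testing.assert_array_equal(p.weights[8:24], 1.0)  # exact central plateau
    assert p.weights[0] == pytest.approx(1 / 9)  # linear ramp, never zero
    assert np.all(p.weights > 0)
    np.testing.assert_array_equal(p.weights, p.weights[::-1])  # symmetry
    assert np.all(np.diff(p.weights[:8]) >= 0)


def test_weight_profile_validation():
    with pytest.raises(ValueError):
        infer.make_weight_profile(32, 18, 8)
    with pytest.raises(ValueError):
        infer.make_weight_profile(32, 16, 8, shape="bogus")


def test_window_starts_cover_and_snap():
    assert infer.window_starts(32, 32) == [0]
    assert infer.window_starts(64, 32, 0.75) == [0, 8, 16, 24, 32]
    starts = infer.window_starts(100, 32, 0.75)
    assert starts[0] == 0 and starts[-1] == 100 - 32
    # every slice covered; slices half a crop away from either end by >= 3
    # windows at stride 8
    cover = np.zeros(100, int)
    for s in starts:
        cover[s:s + 32] += 1
    assert cover.min() >= 1
    assert cover[16:84].min() >= 3


@pytest.mark.parametrize("nz", [32, 40, 64, 100])
def test_sliding_window_conserves_constant_field(nz):
    v = _vol(nz)
    model = ConstantModel((0.5, 0.25, 0.25))
    pv = infer.sliding_window_predict(v, model, crop_z=32)
    assert pv.probs.shape == (3, nz, 16, 16)
    for c, want in enumerate((0.5, 0.25, 0.25)):
        np.testing.assert_allclose(pv.probs[c], want, atol=1e-6)
    np.testing.assert_allclose(pv.probs.sum(axis=0), 1.0, atol=1e-6)


def test_thin_volume_padded_and_unpadded():
    v = _vol(20)
    pv = infer.sliding_window_predict(v, ConstantModel(), crop_z=32)
    assert pv.probs.shape[1] == 20
    np.testing.assert_allclose(pv.probs[0], 0.6, atol=1e-6)


def test_single_window_is_model_output_renormalized():
    v = _vol(32)
    rng = np.random.default_rng(3)
    field = rng.dirichlet(np.ones(3), size=(32, 16, 16)).transpose(3, 0, 1, 2)
    model = lambda crop: field
    pv = infer.sliding_window_predict(v, model, crop_z=32)
    np.testing.assert_allclose(pv.probs, field, atol=1e-6)


def test_ensemble_mean_and_validation():
    v = _vol(32)
    a = ConstantModel((0.8, 0.1, 0.1))
    b = ConstantModel((0.2, 0.5, 0.3))
    pv = infer.ensemble_predict(v, [a, b], crop_z=32)
    np.testing.assert_allclose(pv.probs[0], 0.5, atol=1e-6)
    np.testing.assert_allclose(pv.probs[1], 0.3, atol=1e-6)

    single = infer.ensemble_predict(v, [a], crop_z=32)
    np.testing.assert_allclose(single.probs, infer.sliding_window_predict(v, a, 32).probs,
                               atol=1e-7)
    five = infer.ensemble_predict(v, [a] * 5, crop_z=32)
    np.testing.assert_allclose(five.probs, single.probs, atol=1e-6)
    with pytest.raises(ValueError):
        infer.ensemble_predict(v, [], crop_z=32)


def test_argmax_labels_and_tie_rule(rng):
    probs = rng.dirichlet(np.ones(3), size=(4, 4, 4)).transpose(3, 0, 1, 2)
    pv = infer.ProbabilityVolume(probs, (1.5, 1.5, 5.0))
    labels = infer.argmax_labels(pv).labels
    brute = np.empty((4, 4, 4), np.uint8)
    for idx in np.ndindex(4, 4, 4):
        brute[idx] = int(np.argmax(probs[(slice(None),) + idx]))
    np.testing.assert_array_equal(labels, brute)

    uniform = infer.ProbabilityVolume(np.full((3, 1, 1, 1), 1 / 3), (1, 1, 1))
    assert infer.argmax_labels(uniform).labels[0, 0, 0] == 0  # background wins ties
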