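import numpy as np
import pytest
from scipy.spatial.distance import cdist

from hepavol import tsdf
from hepavol.volume_io import LabelVolume


def brute_force_signed_edt(mask, spacing):
    """O(n²) oracle: per voxel, nearest opposite-region voxel center in mm."""
    mask = np.asarray(mask, bool)
    sx, sy, sz = spacing
    scale = np.array([sz, sy, sx], float)  # (z, y, x) axis order
    coords = np.indices(mask.shape).reshape(3, -1).T * scale
    inside = mask.ravel()
    d = np.empty(mask.size)
    d[inside] = cdist(coords[inside], coords[~inside]).min(axis=1)
    d[~inside] = -cdist(coords[~inside], coords[inside]).min(axis=1)
    return d.reshape(mask.shape)


def test_single_center_voxel_isotropic():
    mask = np.zeros((5, 5, 5), bool)
    mask[2, 2, 2] = True
    d = tsdf.signed_edt(mask, (1, 1, 1))
    assert d[2, 2, 2] == pytest.approx(1.0)
    for nb in [(1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2), (2, 2, 1), (2, 2, 3)]:
        assert d[nb] == pytest.approx(-1.0)


def test_single_center_voxel_anisotropic():
    mask = np.zeros((5, 5, 5), bool)
    mask[2, 2, 2] = True
    d = tsdf.signed_edt(mask, (1, 1, 5))  # (sx, sy, sz)
    assert d[2, 1, 2] == pytest.approx(-1.0)
    assert d[2, 2, 1] == pytest.approx(-1.0)
    assert d[1, 2, 2] == pytest.approx(-5.0)  # z neighbour costs one 5 mm slice


def test_matches_brute_force_on_random_masks(rng):
    for _ in range(25):
        shape = tuple(rng.integers(3, 9, size=3))
        mask = rng.uniform(size=shape) < rng.uniform(0.2, 0.8)
        if not mask.any() or mask.all():
            continue
        spacing = tuple(rng.uniform(0.5, 6.0, size=3))
        got = tsdf.signed_edt(mask, spacing)
        want = brute_force_signed_edt(mask, spacing)
        np.testing.assert_allclose(got, want, atol=1e-9)


def test_sign_antisymmetry(rng):
    mask = rng.uniform(size=(6, 6, 6)) < 0.5
    mask[0, 0, 0], mask[-1, -1, -1] = True, False
    d = tsdf.signed_edt(mask, (1.0, 2.0, 3.0))
    dc = tsdf.signed_edt(~mask, (1.0, 2.0, 3.0))
    # inside/outside swap exactly negates the field (voxel-center metric)
    np.testing.assert_allclose(dc, -d, atol=1e-12)


def test_degenerate_masks_raise():
    with pytest.raises(tsdf.DegenerateMaskError):
        tsdf.signed_edt(np.ones((3, 3, 3), bool), (1, 1, 1))
    with pytest.raises(tsdf.DegenerateMaskError):
        tsdf.signed_edt(np.zeros((3, 3, 3), bool), (1, 1, 1))


@pytest.mark.parametrize("d,expected", [
    (0.0, 0.0), (40.0, 1.0), (-40.0, -1.0), (12.5, 0.5), (-25.0, -1.0), (5.0, 0.2),
])
def test_truncate_rescale_values(d, expected):
    assert tsdf.truncate_rescale(np.array([d]))[0] == pytest.approx(expected)


def test_truncate_rescale_rejects_nonpositive():
    with pytest.raises(ValueError):
        tsdf.truncate_rescale(np.zeros(1), 0.0)


def test_compute_tsdf_absent_class_and_range():
    labels = np.zeros((6, 6, 6), np.uint8)
    labels[2:5, 2:5, 2:5] = 1  # right lobe only
    lv = LabelVolume(labels, (1.5, 1.5, 5.0))
    out = tsdf.compute_tsdf(lv)
    assert out.fields.shape == (2, 6, 6, 6)
    np.testing.assert_array_equal(out.fields[1], -1.0)  # left lobe absent
    assert out.fields.min() >= -1.0 and out.fields.max() <= 1.0


def test_compute_tsdf_deep_interior_saturates():
    # voxel >= 25 mm inside the class maps to exactly +1
    labels = np.zeros((3, 60, 60), np.uint8)
    labels[:, 2:58, 2:58] = 1
    lv = LabelVolume(labels, (1.0, 1.0, 50.0))
    out = tsdf.compute_tsdf(lv)
    assert out.fields[0, 1, 30, 30] == 1.0


def test_compute_tsdf_matches_per_class_oracle(rng):
    labels = np.zeros((8, 8, 8), np.uint8)
    zz = np.indices((8, 8, 8)).sum(axis=0)
    labels[zz > 12] = 1
    labels[(zz > 8) & (zz <= 12)] = 2
    labels[0, 0, 0] = 255  # ignore voxels count as background
    lv = LabelVolume(labels, (2.0, 1.0, 3.0))
    out = tsdf.compute_tsdf(lv)
    for i, c in enumerate((1, 2)):
        want = tsdf.truncate_rescale(
            brute_force_signed_edt(labels == c, lv.spacing), 25.0)
        np.testing.assert_allclose(out.fields[i], want, atol=1e-9)


def test_zero_level_set_at_class_boundary(small_phantom):
    _, lv = small_phantom
    out = tsdf.compute_tsdf(lv)
    for i, c in enumerate((1, 2)):
        inside = lv.labels == c
        assert np.all(out.fields[i][inside] > 0)
        assert np.all(out.fields[i][~inside] < 0)
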