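import math

import numpy as np
import pytest

from octex import GLCM, MVFImage, compute_glcm, glcm_marginals, quantize, texture_features
from octex.texture import FEATURE_ALIASES, FEATURE_NAMES

from glcm_oracle import oracle_features, random_glcm


def image(values, mask=None):
    values = np.asarray(values, float)
    mask = np.ones_like(values, bool) if mask is None else np.asarray(mask, bool)
    return MVFImage(values=values, mask=mask, layer="IPL")


def glcm_from(p, symmetric=True):
    p = np.asarray(p, float)
    return GLCM(
        p=p, n_pairs=100, distance=1, directions=((0, 1),),
        symmetric=symmetric, n_levels=p.shape[0],
    )


class TestQuantize:
    def test_constant_image_all_level_one(self):
        q = quantize(image(np.full((3, 3), 5.0)), n_levels=8)
        assert np.all(q.levels == 1)

    def test_equal_width_bins(self):
        q = quantize(image([[0.0, 85.0, 170.0, 255.0]]), n_levels=4)
        np.testing.assert_array_equal(q.levels, [[1, 2, 3, 4]])

    def test_minmax_maps_extremes(self, rng):
        vals = rng.random((10, 10)) * 100
        q = quantize(image(vals), n_levels=16)
        assert q.levels[vals == vals.min()][0] == 1
        assert q.levels[vals == vals.max()][0] == 16

    def test_affine_invariance(self, rng):
        vals = rng.random((12, 12))
        a, b = 2.0, 64.0  # exact binary arithmetic
        q1 = quantize(image(vals), n_levels=32)
        q2 = quantize(image(a * vals + b), n_levels=32)
        np.testing.assert_array_equal(q1.levels, q2.levels)

    def test_fixed_range(self):
        q = quantize(
            image([[0.0, 5.0, 10.0, 99.0]]), n_levels=2,
            range_mode="fixed", fixed_range=(0.0, 10.0),
        )
        # 5.0 sits exactly on the bin edge and joins the upper bin
        np.testing.assert_array_equal(q.levels, [[1, 2, 2, 2]])

    def test_invalid_args(self):
        img = image([[1.0, 2.0]])
        with pytest.raises(ValueError):
            quantize(img, n_levels=1)
        with pytest.raises(ValueError):
            quantize(img, n_levels=4, range_mode="fixed", fixed_range=(3.0, 3.0))


class TestComputeGLCM:
    def test_row_image_hand_enumeration(self):
        # levels 1,1,2,2 horizontally: ordered pairs (1,1),(1,2),(2,2),
        # symmetrized -> [[1/3, 1/6], [1/6, 1/3]]
        q = quantize(image([[0.0, 0.0, 1.0, 1.0]]), n_levels=2)
        g = compute_glcm(q, directions=((0, 1),))
        np.testing.assert_allclose(
            g.p, [[1 / 3, 1 / 6], [1 / 6, 1 / 3]], rtol=0, atol=1e-15
        )
        assert g.n_pairs == 3

    def test_checkerboard_hand_enumeration(self, checkerboard_image):
        q = quantize(checkerboard_image, n_levels=2)
        g = compute_glcm(q, directions=((0, 1),))
        np.testing.assert_allclose(g.p, [[0.0, 0.5], [0.5, 0.0]], atol=1e-15)

    def test_fully_masked_degenerate(self):
        q = quantize(image(np.ones((4, 4)), mask=np.zeros((4, 4), bool)), n_levels=4)
        g = compute_glcm(q)
        assert g.degenerate and g.n_pairs == 0

    def test_mask_excludes_pairs(self):
        mask = np.ones((1, 4), bool)
        mask[0, 2] = False  # kills pairs (1,2) and (2,3)
        q = quantize(image([[0.0, 0.0, 1.0, 1.0]], mask=mask), n_levels=2)
        g = compute_glcm(q, directions=((0, 1),))
        assert g.n_pairs == 1  # only the (0,1) pair survives

    def test_normalization_and_symmetry(self, rng):
        q = quantize(image(rng.random((16, 16))), n_levels=8)
        g = compute_glcm(q)
        assert abs(g.p.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(g.p, g.p.T, atol=0)
        assert np.all(g.p >= 0)

    def test_agrees_with_skimage_on_unmasked_image(self, rng):
        graycomatrix = pytest.importorskip("skimage.feature").graycomatrix

        lv = rng.integers(0, 8, size=(20, 20)).astype(np.uint8)
        q = quantize(image(lv.astype(float)), n_levels=8)
        ours = compute_glcm(q, directions=((0, 1),), symmetric=True)
        ref = graycomatrix(lv, [1], [0], levels=8, symmetric=True, normed=True)
        np.testing.assert_allclose(ours.p, ref[:, :, 0, 0], atol=1e-12)


class TestMarginals:
    def test_single_cell(self):
        p = np.zeros((3, 3))
        p[0, 0] = 1.0
        m = glcm_marginals(glcm_from(p))
        assert m.mu_x == 1.0 and m.sigma_x == 0.0
        assert m.hx == m.hxy == m.hxy2 == 0.0

    def test_checkerboard_marginals(self):
        m = glcm_marginals(glcm_from([[0.0, 0.5], [0.5, 0.0]]))
        assert m.p_sum[1] == 1.0  # P(i+j = 3)
        assert m.p_diff[1] == 1.0  # P(|i-j| = 1)
        assert m.mu_x == 1.5

    def test_symmetric_glcm_equal_marginals(self, rng):
        p = random_glcm(6, rng)
        m = glcm_marginals(glcm_from(p))
        np.testing.assert_allclose(m.p_x, m.p_y, atol=1e-15)
        for dist in (m.p_x, m.p_y, m.p_sum, m.p_diff):
            assert abs(dist.sum() - 1.0) < 1e-12

    def test_degenerate_rejected(self):
        g = GLCM(np.zeros((2, 2)), 0, 1, ((0, 1),), True, 2)
        with pytest.raises(ValueError):
            glcm_marginals(g)


CONSTANT_EXPECTED = {
    "contrast": 0.0,
    "angular_second_moment": 1.0,
    "inverse_difference_moment": 1.0,
    "entropy": 0.0,
    "dissimilarity": 0.0,
    "maximum_probability": 1.0,
    "autocorrelation": 1.0,
    "sum_average": 2.0,
    "sum_variance": 0.0,
    "sum_entropy": 0.0,
    "sum_of_squares_variance": 0.0,
    "difference_variance": 0.0,
    "difference_entropy": 0.0,
    "cluster_shade": 0.0,
    "cluster_prominence": 0.0,
    "imci": 0.0,
    "imcii": 0.0,
    "inn": 1.0,
    "idn": 1.0,
    "correlation": 1.0,  # degenerate-case convention
}

CHECKERBOARD_EXPECTED = {
    "contrast": 1.0,
    "dissimilarity": 1.0,
    "angular_second_moment": 0.5,
    "inverse_difference_moment": 0.5,
    "correlation": -1.0,
    "entropy": 1.0,  # bits
    "maximum_probability": 0.5,
    "autocorrelation": 2.0,
    "sum_average": 3.0,
    "sum_variance": 0.0,
    "cluster_shade": 0.0,
    "cluster_prominence": 0.0,
    "inn": 2.0 / 3.0,
    "idn": 0.8,
}


class TestTextureFeatures:
    def test_exactly_twenty_named_features(self):
        assert len(FEATURE_NAMES) == 20
        f = texture_features(glcm_from(np.eye(4) / 4.0))
        assert tuple(f.values) == FEATURE_NAMES
        assert set(FEATURE_ALIASES) <= set(FEATURE_NAMES)

    def test_constant_image_analytic_vector(self):
        img = image(np.full((6, 6), 3.0))
        f = texture_features(compute_glcm(quantize(img, n_levels=64)))
        for name, expected in CONSTANT_EXPECTED.items():
            assert f[name] == pytest.approx(expected, abs=1e-12), name

    def test_checkerboard_hand_values(self, checkerboard_image):
        g = compute_glcm(quantize(checkerboard_image, 2), directions=((0, 1),))
        f = texture_features(g)
        for name, expected in CHECKERBOARD_EXPECTED.items():
            assert f[name] == pytest.approx(expected, abs=1e-12), name

    def test_degenerate_glcm_yields_nan_markers(self):
        g = GLCM(np.zeros((2, 2)), 0, 1, ((0, 1),), True, 2)
        f = texture_features(g)
        assert all(math.isnan(v) for v in f.values.values())

    @pytest.mark.parametrize("ng", [4, 16, 64])
    def test_brute_force_oracle_agreement(self, ng, rng):
        for _ in range(10):
            p = random_glcm(ng, rng)
            ours = texture_features(glcm_from(p)).values
            ref = oracle_features(p.tolist())
            for name in FEATURE_NAMES:
                assert ours[name] == pytest.approx(ref[name], rel=1e-10, abs=1e-12), name

    def test_bounds_on_random_glcms(self, rng):
        for ng in (4, 16):
            for _ in range(20):
                f = texture_features(glcm_from(random_glcm(ng, rng)))
                assert f.defined
                assert 0.0 <= f["angular_second_moment"] <= 1.0
                assert 0.0 <= f["maximum_probability"] <= 1.0
                assert -1.0 - 1e-12 <= f["correlation"] <= 1.0 + 1e-12
                assert 0.0 <= f["imcii"] <= 1.0
                for name in ("inverse_difference_moment", "inn", "idn"):
                    assert 0.0 < f[name] <= 1.0

    def test_transpose_invariance(self, rng):
        p = random_glcm(8, rng)
        a = texture_features(glcm_from(p)).values
        b = texture_features(glcm_from(p.T)).values
        for name in FEATURE_NAMES:
            assert a[name] == pytest.approx(b[name], rel=1e-12)

    def test_affine_intensity_invariance_end_to_end(self, rng):
        vals = rng.random((20, 20))
        f1 = texture_features(compute_glcm(quantize(image(vals), 16))).values
        f2 = texture_features(
            compute_glcm(quantize(image(4.0 * vals + 100.0), 16))
        ).values
        for name in FEATURE_NAMES:
            assert f1[name] == pytest.approx(f2[name], rel=1e-12)


def test_monotone_sensitivity_to_speckle_correlation():
    """Coarser speckle (longer correlation) -> higher GLCM correlation and
    IDM, lower contrast, monotone over a 5-point sweep of 20 seeds each."""
    from octex import speckle_field

    sweeps = {"correlation": [], "inverse_difference_moment": [], "contrast": []}
    for corr_len in (0.5, 1.0, 1.5, 2.0, 3.0):
        acc = {k: 0.0 for k in sweeps}
        for s in range(20):
            fld = speckle_field((48, 48, 1), 0.35, corr_len, np.random.default_rng(500 + s))
            f = texture_features(compute_glcm(quantize(image(fld[:, :, 0]), 32)))
            for k in acc:
                acc[k] += f[k] / 20.0
        for k in sweeps:
            sweeps[k].append(acc[k])
    assert np.all(np.diff(sweeps["correlation"]) > 0)
    assert np.all(np.diff(sweeps["inverse_difference_moment"]) > 0)
    assert np.all(np.diff(sweeps["contrast"]) < 0)
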