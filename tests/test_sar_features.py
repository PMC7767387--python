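"""SAR feature math: dB conversion, eigendecomposition, H/A/Alpha, span,
Shannon entropy, channel combinations and the Lee filter."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lodgemap.geo import GridTransform
from lodgemap.sar import (
    C2Raster,
    eigen_c2,
    entropy_anisotropy_alpha,
    feature_stack,
    lee_filter,
    shannon_entropy,
    sigma_combinations,
    span,
    to_db,
)
from conftest import random_psd_c2


def c2_of(c11, c22, c12):
    return C2Raster(
        c11=np.atleast_1d(np.asarray(c11, dtype=float)),
        c22=np.atleast_1d(np.asarray(c22, dtype=float)),
        c12=np.atleast_1d(np.asarray(c12, dtype=complex)),
    )


class TestToDb:
    @pytest.mark.parametrize(
        "power,expected",
        [(1.0, 0.0), (10.0, 10.0), (0.059566, -12.25)],
    )
    def test_known_conversions(self, power, expected):
        assert to_db(np.array([power]))[0] == pytest.approx(expected, abs=5e-3)

    def test_nonpositive_pixels_floored(self):
        out = to_db(np.array([0.0, -1.0, 1.0]), floor_db=-50.0)
        assert out[0] == -50.0 and out[1] == -50.0 and out[2] == 0.0


class TestEigen:
    def test_diagonal_case(self):
        lam1, lam2, a1, a2 = eigen_c2(c2_of(2.0, 1.0, 0.0))
        assert lam1[0] == pytest.approx(2.0) and lam2[0] == pytest.approx(1.0)
        # dominant eigenvector is e_vv -> alpha1 = 0, the other e_vh -> pi/2
        assert a1[0] == pytest.approx(0.0) and a2[0] == pytest.approx(np.pi / 2)

    def test_rank_one_symmetric(self):
        lam1, lam2, a1, _ = eigen_c2(c2_of(1.0, 1.0, 1.0))
        assert lam1[0] == pytest.approx(2.0) and lam2[0] == pytest.approx(0.0, abs=1e-12)
        assert a1[0] == pytest.approx(np.pi / 4)

    def test_matches_numerical_eigensolver(self, rng):
        c11, c22, c12 = random_psd_c2(rng, 1000)
        lam1, lam2, a1, a2 = eigen_c2(c2_of(c11, c22, c12))
        for i in range(1000):
            m = np.array([[c11[i], c12[i]], [np.conj(c12[i]), c22[i]]])
            w, v = np.linalg.eigh(m)
            assert abs(lam1[i] - w[1]) < 1e-10 * max(1.0, w[1])
            assert abs(lam2[i] - w[0]) < 1e-10 * max(1.0, w[1])
            if w[1] - w[0] > 1e-3 * w[1]:  # alpha ill-conditioned near degeneracy
                assert a1[i] == pytest.approx(np.arccos(np.abs(v[0, 1])), abs=1e-8)
                assert a2[i] == pytest.approx(np.arccos(np.abs(v[0, 0])), abs=1e-8)


class TestEntropyAnisotropyAlpha:
    def test_equal_eigenvalues_maximal_mixing(self):
        d = entropy_anisotropy_alpha(np.array([2.0]), np.array([2.0]), np.array([0.3]), np.array([0.7]))
        assert d.entropy[0] == pytest.approx(1.0)
        assert d.anisotropy[0] == pytest.approx(0.0)
        assert d.alpha_mean[0] == pytest.approx(0.5)

    def test_rank_one_pure_state(self):
        d = entropy_anisotropy_alpha(np.array([3.0]), np.array([0.0]), np.array([0.2]), np.array([1.0]))
        assert d.entropy[0] == pytest.approx(0.0)
        assert d.anisotropy[0] == pytest.approx(1.0)
        assert d.alpha_mean[0] == pytest.approx(0.2)

    def test_three_one_split(self):
        expected = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        d = entropy_anisotropy_alpha(np.array([3.0]), np.array([1.0]), np.array([0.0]), np.array([0.0]))
        assert d.entropy[0] == pytest.approx(expected)
        assert expected == pytest.approx(0.8113, abs=1e-4)

    def test_bounds_on_random_matrices(self, rng):
        c11, c22, c12 = random_psd_c2(rng, 10_000)
        d = entropy_anisotropy_alpha(*eigen_c2(c2_of(c11, c22, c12)))
        assert np.all((d.entropy >= -1e-12) & (d.entropy <= 1 + 1e-12))
        assert np.all((d.anisotropy >= -1e-12) & (d.anisotropy <= 1 + 1e-12))

    @given(st.floats(0.01, 100.0))
    def test_entropy_invariant_to_scaling(self, k):
        lam1, lam2 = np.array([3.0]), np.array([1.0])
        a = np.array([0.4])
        h0 = entropy_anisotropy_alpha(lam1, lam2, a, a).entropy[0]
        hk = entropy_anisotropy_alpha(k * lam1, k * lam2, a, a).entropy[0]
        assert hk == pytest.approx(h0, abs=1e-12)


class TestSpan:
    def test_identity_trace_mode(self):
        c2 = c2_of(1.0, 1.0, 0.0)
        assert span(c2, in_db=False)[0] == pytest.approx(2.0)
        assert span(c2)[0] == pytest.approx(10 * np.log10(2.0), abs=1e-6)

    def test_reference_vv_vh_powers(self):
        # linear powers equivalent to -12.25 and -17.13 dB
        c2 = c2_of(0.059566, 0.019365, 0.0)
        assert span(c2)[0] == pytest.approx(-11.03, abs=0.01)

    def test_squared_mode_identity(self):
        assert span(c2_of(1.0, 1.0, 0.0), mode="squared", in_db=False)[0] == pytest.approx(2.0)

    def test_trace_mode_scales_linearly(self):
        c2a = c2_of(0.5, 0.3, 0.1)
        c2b = c2_of(1.5, 0.9, 0.3)
        assert span(c2b, in_db=False)[0] == pytest.approx(3 * span(c2a, in_db=False)[0])


class TestShannonEntropy:
    def test_identity_matrix(self):
        assert shannon_entropy(c2_of(1.0, 1.0, 0.0))[0] == pytest.approx(2 * np.log(np.pi * np.e), abs=1e-4)
        assert shannon_entropy(c2_of(1.0, 1.0, 0.0))[0] == pytest.approx(4.2895, abs=1e-3)

    def test_rank_one_hits_floor_finite(self):
        se = shannon_entropy(c2_of(1.0, 1.0, 1.0))[0]
        assert np.isfinite(se) and se < shannon_entropy(c2_of(1.0, 1.0, 0.0))[0] - 10

    @pytest.mark.parametrize("k", [0.1, 2.0, 50.0])
    def test_scaling_shifts_by_2_log_k(self, k):
        base = c2_of(0.6, 0.4, 0.2 + 0.1j)
        scaled = c2_of(0.6 * k, 0.4 * k, (0.2 + 0.1j) * k)
        assert shannon_entropy(scaled)[0] - shannon_entropy(base)[0] == pytest.approx(2 * np.log(k), abs=1e-9)


class TestSigmaCombinations:
    def test_reference_sum_and_ratio(self):
        s = sigma_combinations(np.array([-12.25]), np.array([-17.13]))
        assert s.vv_plus_vh[0] == pytest.approx(-29.38)
        assert s.vv_minus_vh[0] == pytest.approx(4.88)
        assert s.vh_over_vv[0] == pytest.approx(1.398, abs=1e-3)

    def test_equal_inputs_ratio_one(self):
        s = sigma_combinations(np.array([-12.25]), np.array([-12.25]))
        assert s.vh_over_vv[0] == pytest.approx(1.0)

    def test_exact_reconstruction(self, rng):
        vv = rng.normal(-12, 3, size=100)
        vh = rng.normal(-17, 3, size=100)
        s = sigma_combinations(vv, vh)
        assert np.array_equal(s.vv_plus_vh, vv + vh)  # exact per-pixel arithmetic
        assert np.array_equal(s.vv_minus_vh, vv - vh)
        np.testing.assert_allclose((s.vv_plus_vh + s.vv_minus_vh) / 2, vv, rtol=0, atol=1e-12)
        np.testing.assert_allclose((s.vv_plus_vh - s.vv_minus_vh) / 2, vh, rtol=0, atol=1e-12)

    def test_zero_vv_ratio_undefined(self):
        s = sigma_combinations(np.array([0.0]), np.array([-17.0]))
        assert np.isnan(s.vh_over_vv[0])


class TestLeeFilter:
    def test_constant_grid_unchanged(self):
        g = np.full((20, 20), 7.0)
        np.testing.assert_allclose(lee_filter(g, 3, enl=4), g)

    def test_variance_reduced_on_speckle(self, rng):
        mean = np.full((64, 64), 0.05)
        speckled = mean * rng.gamma(4.0, 0.25, size=mean.shape)
        filtered = lee_filter(speckled, 3, enl=4)
        assert filtered.var() < speckled.var()

    def test_bright_point_attenuated_mean_conserved(self):
        g = np.full((21, 21), 1.0)
        g[10, 10] = 100.0
        out = lee_filter(g, 3, enl=4)
        assert out[10, 10] < g[10, 10]
        assert out.mean() == pytest.approx(g.mean(), rel=0.01)

    @pytest.mark.parametrize("window", [2, 4, 1])
    def test_even_or_too_small_window_rejected(self, window):
        with pytest.raises(ValueError):
            lee_filter(np.ones((5, 5)), window)


class TestFeatureStack:
    def test_band_names_and_bounds(self, small_scene):
        stack = feature_stack(small_scene.sar_after, enl=small_scene.config.enl)
        assert stack.names == [
            "VV", "VH", "VV + VH", "VV − VH", "VH/VV",
            "Alpha", "Anisotropy", "Entropy", "Shannon Entropy", "Span",
        ]
        h, a = stack["Entropy"], stack["Anisotropy"]
        ok = np.isfinite(h)
        assert np.all((h[ok] >= 0) & (h[ok] <= 1))
        assert np.all((a[ok] >= 0) & (a[ok] <= 1))

    def test_psd_validation_rejects_bad_matrix(self):
        with pytest.raises(ValueError):
            C2Raster(c11=np.array([[1.0]]), c22=np.array([[1.0]]), c12=np.array([[2.0 + 0j]]))
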