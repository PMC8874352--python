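"""Histograms, Gaussian fits, chi-square distance, and group tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blinkhazard import distfit as D
from conftest import epochs_from_latencies


class TestBinAndSmooth:
    def test_single_blink(self):
        d = D.bin_and_smooth(epochs_from_latencies([10.0]))
        assert d.pristine[0] == 1.0
        assert d.pristine[1:].sum() == 0.0
        assert d.n_blinks == 1

    def test_normalization_conservation(self):
        rng = np.random.default_rng(0)
        d = D.bin_and_smooth(
            epochs_from_latencies(rng.uniform(0, 3500, 500)))
        assert d.pristine.sum() == pytest.approx(1.0)
        assert len(d.pristine) == 175

    def test_uniform_latencies_flat(self):
        rng = np.random.default_rng(1)
        d = D.bin_and_smooth(
            epochs_from_latencies(rng.uniform(0, 3500, 10000)))
        assert np.allclose(d.smoothed, 1 / 175, atol=2e-3)

    def test_edge_values_go_right(self):
        d = D.bin_and_smooth(epochs_from_latencies([20.0, 40.0]))
        assert d.counts[1] == 1 and d.counts[2] == 1
        assert d.counts[0] == 0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            D.bin_and_smooth(epochs_from_latencies([3500.0]))

    def test_empty_flagged(self):
        d = D.bin_and_smooth(epochs_from_latencies([]))
        assert d.empty and d.pristine.sum() == 0

    def test_moving_median_shrinks_at_edges(self):
        x = np.array([10.0, 0, 0, 0, 0, 0, 10.0])
        sm = D.moving_median(x)
        # first window is x[0:3] -> median 0; interior windows of 5
        assert sm[0] == 0.0 and sm[-1] == 0.0
        assert np.all(sm[2:5] == 0.0)


class TestGroupMedian:
    def test_identity(self):
        c = np.random.default_rng(2).uniform(size=(1, 175))
        np.testing.assert_array_equal(D.group_median_distribution(c), c[0])

    def test_pointwise_median_odd(self):
        c = np.array([[1.0, 5.0], [2.0, 4.0], [3.0, 3.0]])
        np.testing.assert_array_equal(D.group_median_distribution(c),
                                      [2.0, 4.0])

    def test_even_count_midpoint_average(self):
        c = np.array([[1.0], [2.0], [3.0], [10.0]])
        assert D.group_median_distribution(c)[0] == 2.5


class TestFitFiveGaussians:
    def test_noiseless_recovery(self):
        true = np.array([375, 25, 0.02, 1125, 30, 0.03, 1875, 25, 0.04,
                         2625, 30, 0.03, 3375, 25, 0.02])
        curve = D._gauss_sum(true, D.BIN_CENTERS)
        fit = D.fit_five_gaussians(curve)
        means = np.sort(fit.means_ms)
        np.testing.assert_allclose(means, true[0::3], atol=5.0)
        amps = fit.amplitudes[np.argsort(fit.means_ms)]
        np.testing.assert_allclose(amps, true[2::3], rtol=0.01)
        assert fit.mean_residual < 1e-8

    def test_all_zero_curve(self):
        fit = D.fit_five_gaussians(np.zeros(175))
        assert np.all(fit.amplitudes == 0) and fit.mean_residual == 0

    def test_single_gaussian_dominant_amplitude(self):
        curve = 0.05 * np.exp(-0.5 * ((D.BIN_CENTERS - 1875) / 40.0) ** 2)
        fit = D.fit_five_gaussians(curve)
        order = np.argsort(np.abs(fit.amplitudes))[::-1]
        assert abs(fit.means_ms[order[0]] - 1875) < 30
        assert np.abs(fit.amplitudes[order[0]]) > \
            10 * np.abs(fit.amplitudes[order[1]])

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            D.fit_five_gaussians(np.zeros(100))


class TestChi2Distance:
    def test_printed_style_values(self):
        assert D.chi2_distance([2.0, 0.0], [0.0, 2.0]) == pytest.approx(2.0)
        assert D.chi2_distance([1.0, 0.0], [0.0, 0.0]) == pytest.approx(0.5)
        assert D.chi2_distance([1.0, 1.0], [1.0, 1.0]) == 0.0

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            D.chi2_distance([-1.0], [1.0])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_nonnegativity_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, 20)
        y = rng.uniform(0, 1, 20)
        dxy = D.chi2_distance(x, y)
        assert dxy >= 0
        assert dxy == pytest.approx(D.chi2_distance(y, x))
        assert D.chi2_distance(x, x) == 0.0
        if not np.array_equal(x, y):
            assert dxy > 0


class TestBootstrapDistance:
    def test_identical_groups_distance_zero(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(size=(4, 175))
        res = D.bootstrap_distance_test(g, g.copy(), n=99, seed=0)
        assert res.distance == 0.0
        assert res.p_value == 1.0

    def test_disjoint_groups_minimal_p(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 0.01, size=(6, 175))
        a[:, 10:20] += 0.1
        b = rng.uniform(0, 0.01, size=(6, 175))
        b[:, 150:160] += 0.1
        res = D.bootstrap_distance_test(a, b, n=400, seed=1)
        assert res.p_value < 0.02

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(4)
        res = D.bootstrap_distance_test(rng.uniform(size=(4, 175)),
                                        rng.uniform(size=(4, 175)),
                                        n=50, seed=2)
        assert 0 < res.p_value <= 1.0

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            D.bootstrap_distance_test(np.zeros((1, 175)),
                                      np.zeros((2, 175)))


class TestPerIntervalPeakTests:
    def _fit_at_midpoints(self):
        return D.GaussianFit(
            means_ms=np.array(D.INTERVAL_MIDPOINTS_MS),
            sigmas_ms=np.full(5, 20.0), amplitudes=np.full(5, 0.02),
            iterations=0, mean_residual=0.0, converged=True)

    def test_identical_groups_all_nonsignificant(self):
        rng = np.random.default_rng(5)
        g = rng.uniform(0, 0.02, size=(10, 175))
        rep = D.per_interval_peak_tests(g, g.copy(), self._fit_at_midpoints())
        assert all(p > 0.9 for p in rep["p_fdr"])

    def test_suppression_only_in_s3(self):
        rng = np.random.default_rng(6)
        base = 0.01
        a = base + rng.normal(0, 0.001, size=(15, 175))
        b = base + rng.normal(0, 0.001, size=(15, 175))
        s3_bin = int(D.INTERVAL_MIDPOINTS_MS[2] // 20)
        b[:, s3_bin] -= 0.006
        rep = D.per_interval_peak_tests(a, b, self._fit_at_midpoints())
        sig = [iv for iv, p in zip(rep["intervals"], rep["p_fdr"])
               if p < 0.05]
        assert sig == ["S3"]

    def test_bh_adjustment_hand_checked(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(size=(8, 175))
        b = rng.uniform(size=(8, 175))
        rep = D.per_interval_peak_tests(a, b, self._fit_at_midpoints())
        raw = np.array(rep["p_raw"])
        m = len(raw)
        order = np.argsort(raw)
        # hand BH: p_(i) * m / i with monotone enforcement from the largest
        stepped = raw[order] * m / np.arange(1, m + 1)
        hand = np.minimum.accumulate(stepped[::-1])[::-1]
        hand = np.minimum(hand, 1.0)
        expected = np.empty(m)
        expected[order] = hand
        np.testing.assert_allclose(rep["p_fdr"], expected)

    def test_out_of_range_peak_skipped(self):
        fit = D.GaussianFit(means_ms=np.array([375.0, 4000.0, 1125.0,
                                               1875.0, 2625.0]),
                            sigmas_ms=np.full(5, 20.0),
                            amplitudes=np.full(5, 0.02),
                            iterations=0, mean_residual=0.0, converged=True)
        g = np.random.default_rng(8).uniform(size=(5, 175))
        with pytest.warns(UserWarning, match="outside"):
            rep = D.per_interval_peak_tests(g, g.copy(), fit)
        assert len(rep["intervals"]) == 4
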