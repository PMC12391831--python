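"""Detrending, chronology building, and chronology statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ghostforest import (
    IndexSeries,
    RingWidthSeries,
    build_chronology,
    detrend,
    eps_from_snr,
    fit_detrend,
    interseries_correlation,
    mean_sensitivity,
    rbar_eps_snr,
)
from ghostforest.chronology import HORIZONTAL_MEAN, NEGATIVE_EXPONENTIAL, tukey_biweight_mean


class TestFitDetrend:
    def test_negexp_coefficients_recovered_exactly(self, negexp_series):
        fit = fit_detrend(negexp_series)
        assert fit.model == NEGATIVE_EXPONENTIAL
        assert abs(fit.params["a"] - 2.0) < 1e-6
        assert abs(fit.params["b"] - 0.05) < 1e-6
        assert abs(fit.params["k"] - 0.5) < 1e-6

    def test_constant_series_horizontal_mean(self, constant_series):
        fit = fit_detrend(constant_series)
        assert fit.model == HORIZONTAL_MEAN
        np.testing.assert_allclose(fit.fitted, 1.2)

    def test_increasing_series_falls_back_to_horizontal_mean(self):
        s = RingWidthSeries("UP", 1900, np.linspace(0.5, 2.0, 50))
        fit = fit_detrend(s)
        assert fit.model == HORIZONTAL_MEAN

    def test_all_zero_series_raises(self):
        s = RingWidthSeries("Z", 1900, np.zeros(20))
        with pytest.raises(ValueError, match="all-zero"):
            fit_detrend(s)

    def test_too_short_raises(self):
        s = RingWidthSeries("S", 1900, np.ones(5))
        with pytest.raises(ValueError, match="10"):
            fit_detrend(s)


class TestDetrend:
    def test_series_equal_to_fit_gives_unit_index(self, negexp_series):
        idx = detrend(negexp_series, fit_detrend(negexp_series))
        np.testing.assert_allclose(idx.index, 1.0, atol=1e-6)

    def test_zero_width_gives_zero_index(self):
        w = np.ones(30)
        w[10] = 0.0
        idx = detrend(RingWidthSeries("Z1", 1900, w))
        assert idx.index[10] == 0.0

    def test_lognormal_noise_mean_near_one(self, rng):
        t = np.arange(120, dtype=float)
        curve = 2.0 * np.exp(-0.03 * t) + 0.4
        w = curve * np.exp(rng.normal(0, 0.2, 120))
        idx = detrend(RingWidthSeries("LN", 1850, w))
        assert abs(idx.index.mean() - 1.0) < 0.05

    @pytest.mark.parametrize("c", [0.1, 3.0, 250.0])
    def test_scale_equivariance(self, negexp_series, rng, c):
        """Multiplying all widths by c > 0 leaves the index unchanged."""
        noisy = negexp_series.widths * np.exp(rng.normal(0, 0.1, len(negexp_series)))
        base = detrend(RingWidthSeries("A", 1900, noisy))
        scaled = detrend(RingWidthSeries("B", 1900, c * noisy))
        np.testing.assert_allclose(scaled.index, base.index, rtol=1e-5)


class TestMeanSensitivity:
    def test_constant_series_is_zero(self, constant_series):
        assert mean_sensitivity(constant_series) == 0.0

    def test_alternating_series_exact(self):
        """1,2,1,2,...: every term |2*1/3| -> MS = 2/3 exactly."""
        x = np.tile([1.0, 2.0], 10)
        assert mean_sensitivity(x) == pytest.approx(2.0 / 3.0, abs=1e-15)

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        x = np.array([1.0, 0.4, 2.2, 1.8, 0.9])
        assert mean_sensitivity(c * x) == pytest.approx(mean_sensitivity(x), rel=1e-12)

    def test_zero_pair_raises(self):
        with pytest.raises(ValueError, match="zero"):
            mean_sensitivity(np.array([1.0, 0.0, 0.0, 1.0]))

    def test_matches_bruteforce_oracle(self, rng):
        x = np.exp(rng.normal(0, 0.3, 40))
        expected = np.mean([abs(2 * (x[i + 1] - x[i]) / (x[i + 1] + x[i])) for i in range(39)])
        assert mean_sensitivity(x) == pytest.approx(expected, abs=1e-12)


def _make_indices(rng, n=5, years=50, lam=0.5, first_year=1950):
    """Series sharing a common signal with mixing fraction lam."""
    common = rng.normal(0, 1, years)
    out = []
    for i in range(n):
        noise = rng.normal(0, 1, years)
        sig = lam * common + (1 - lam) * noise
        out.append(IndexSeries(f"I{i}", first_year, 1.0 + 0.1 * (sig - sig.min())))
    return out


class TestInterseriesCorrelation:
    def test_identical_series_give_unit_correlation(self, rng):
        base = IndexSeries("A", 1950, 1.0 + 0.2 * rng.random(40))
        copies = [IndexSeries(f"C{i}", 1950, base.index) for i in range(3)]
        per, mean = interseries_correlation(copies)
        assert all(r == pytest.approx(1.0) for r in per.values())
        assert mean == pytest.approx(1.0)

    def test_opposite_pattern_negative(self):
        a = np.array([1.0, 1.4] * 15)
        b = np.array([1.4, 1.0] * 15)
        per, _ = interseries_correlation([IndexSeries("A", 1950, a), IndexSeries("B", 1950, b)])
        assert per["A"] < 0

    def test_matches_leave_one_out_oracle(self, rng):
        """Brute-force oracle: per-series r against the mean of the others."""
        indices = _make_indices(rng, n=5, years=50, lam=0.5)
        per, mean = interseries_correlation(indices)
        mat = np.vstack([s.index for s in indices])
        expected = []
        for i in range(5):
            loo = np.delete(mat, i, axis=0).mean(axis=0)
            expected.append(np.corrcoef(mat[i], loo)[0, 1])
        for r, e in zip(per.values(), expected):
            assert r == pytest.approx(e, abs=1e-12)
        assert mean == pytest.approx(np.mean(expected), abs=1e-12)

    def test_increases_with_common_signal(self):
        r_weak = interseries_correlation(_make_indices(np.random.default_rng(0), lam=0.2))[1]
        r_strong = interseries_correlation(_make_indices(np.random.default_rng(0), lam=0.8))[1]
        assert r_strong > r_weak

    def test_short_overlap_flagged(self, rng):
        long1 = IndexSeries("L1", 1900, 1 + 0.1 * rng.random(100))
        long2 = IndexSeries("L2", 1900, 1 + 0.1 * rng.random(100))
        short = IndexSeries("SH", 1990, 1 + 0.1 * rng.random(10))
        with pytest.warns(UserWarning, match="SH"):
            per, _ = interseries_correlation([long1, long2, short])
        assert np.isnan(per["SH"])


class TestRbarEpsSnr:
    def test_matches_all_pairs_oracle(self, rng):
        indices = _make_indices(rng, n=6, years=50, lam=0.6)
        rbar, eps, snr = rbar_eps_snr(indices)
        mat = np.vstack([s.index for s in indices])
        rs = [
            np.corrcoef(mat[i], mat[j])[0, 1]
            for i in range(6)
            for j in range(i + 1, 6)
        ]
        expected_rbar = np.mean(rs)
        n = 6
        assert rbar == pytest.approx(expected_rbar, abs=1e-12)
        assert eps == pytest.approx(n * expected_rbar / (1 + (n - 1) * expected_rbar), abs=1e-12)
        assert snr == pytest.approx(n * expected_rbar / (1 - expected_rbar), abs=1e-12)

    def test_eps_snr_identity_machine_precision(self, rng):
        _, eps, snr = rbar_eps_snr(_make_indices(rng))
        assert eps == pytest.approx(snr / (1 + snr), abs=1e-15)

    def test_perfect_agreement_gives_unit_eps_and_infinite_snr(self):
        base = np.array([1.0, 1.2, 0.8, 1.1] * 10)
        copies = [IndexSeries(f"C{i}", 1950, base) for i in range(3)]
        rbar, eps, snr = rbar_eps_snr(copies)
        assert rbar == pytest.approx(1.0)
        assert eps == pytest.approx(1.0)
        assert np.isinf(snr)
        assert eps_from_snr(snr) == 1.0

    def test_window_restricts_years(self, rng):
        indices = _make_indices(rng, n=3, years=60, first_year=1940)
        full = rbar_eps_snr(indices)[0]
        windowed = rbar_eps_snr(indices, window=(1960, 1999))[0]
        assert windowed != pytest.approx(full)


class TestBuildChronology:
    def test_single_series_identity(self, rng):
        idx = IndexSeries("A", 1950, 1 + 0.2 * rng.random(30))
        chron = build_chronology([idx], method="mean")
        np.testing.assert_array_equal(chron.values, idx.index)
        assert (chron.depth == 1).all()

    def test_copies_return_the_series(self, rng):
        idx = IndexSeries("A", 1950, 1 + 0.2 * rng.random(30))
        copies = [IndexSeries(f"C{i}", 1950, idx.index) for i in range(4)]
        chron = build_chronology(copies, method="mean")
        np.testing.assert_allclose(chron.values, idx.index)

    def test_two_series_hand_mean(self):
        a = IndexSeries("A", 2000, np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        b = IndexSeries("B", 2000, np.array([3.0, 2.0, 1.0, 0.0, 1.0]))
        chron = build_chronology([a, b], method="mean")
        np.testing.assert_allclose(chron.values, [2.0, 2.0, 2.0, 2.0, 3.0])

    def test_truncation_start_year(self, rng):
        idx = IndexSeries("A", 1700, 1 + 0.1 * rng.random(400))
        other = IndexSeries("B", 1700, 1 + 0.1 * rng.random(400))
        chron = build_chronology([idx, other], truncate_start=1850)
        assert chron.first_year == 1850

    def test_empty_after_truncation_raises(self, rng):
        idx = IndexSeries("A", 1900, 1 + 0.1 * rng.random(30))
        with pytest.raises(ValueError, match="truncate"):
            build_chronology([idx], truncate_start=2000)

    def test_biweight_downweights_outlier(self):
        col = np.array([1.0, 1.02, 0.98, 1.01, 0.99, 8.0])
        assert abs(tukey_biweight_mean(col) - 1.0) < 0.05
        assert abs(col.mean() - 1.0) > 1.0

    def test_depth_counts_covering_series(self, rng):
        a = IndexSeries("A", 1950, 1 + 0.1 * rng.random(30))
        b = IndexSeries("B", 1960, 1 + 0.1 * rng.random(30))
        chron = build_chronology([a, b], method="mean")
        assert chron.depth[chron.years < 1960].max() == 1
        assert chron.depth[(chron.years >= 1960) & (chron.years <= 1979)].min() == 2
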