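"""Water-yield-coefficient regressions against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import flowattrib as fa
from flowattrib.water_yield import (
    compare_wyc,
    detrend,
    linear_trend,
    partial_wyc,
    water_yield_coefficient,
)

YEARS = np.arange(1982, 2013)
RNG = np.random.default_rng(42)


class TestLinearTrend:
    def test_constant_series_has_zero_slope(self):
        slope, intercept = linear_trend(YEARS, np.full(YEARS.size, 7.0))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(7.0, rel=1e-9)

    def test_exact_linear_series(self):
        slope, _ = linear_trend(YEARS, 2.0 * (YEARS - 1982))
        assert slope == pytest.approx(2.0, abs=1e-10)

    def test_matches_covariance_ratio(self):
        values = RNG.normal(size=YEARS.size)
        slope, _ = linear_trend(YEARS, values)
        x = YEARS - YEARS.mean()
        oracle = float(x @ (values - values.mean()) / (x @ x))
        assert slope == pytest.approx(oracle, abs=1e-10)

    def test_identical_years_singular(self):
        with pytest.raises(fa.SingularDesignError):
            linear_trend(np.full(5, 1990), np.arange(5.0))


class TestDetrend:
    def test_trend_free_series_unchanged(self):
        values = RNG.normal(size=YEARS.size)
        flat = detrend(YEARS, values)
        np.testing.assert_allclose(detrend(YEARS, flat), flat, atol=1e-10)  # idempotent
        slope, _ = linear_trend(YEARS, flat)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_pure_linear_becomes_its_mean(self):
        values = 3.0 * YEARS + 5.0
        np.testing.assert_allclose(detrend(YEARS, values), values.mean(), atol=1e-7)

    @given(st.integers(0, 2**31 - 1))
    def test_mean_preserved(self, seed):
        values = np.random.default_rng(seed).normal(50, 10, size=12)
        years = np.arange(2001, 2013)
        assert detrend(years, values).mean() == pytest.approx(values.mean(), abs=1e-10)


class TestWaterYieldCoefficient:
    def test_exact_proportionality(self):
        P = RNG.uniform(200, 400, size=20)
        res = water_yield_coefficient(P, 0.5 * P)
        assert res.slope == pytest.approx(0.5, abs=1e-10)
        assert res.p_value < 1e-12

    def test_slope_equals_covariance_ratio(self):
        P = RNG.uniform(200, 400, size=25)
        Q = RNG.normal(60, 15, size=25)
        res = water_yield_coefficient(P, Q)
        oracle = np.cov(P, Q, ddof=1)[0, 1] / np.var(P, ddof=1)
        assert res.slope == pytest.approx(oracle, abs=1e-10)

    def test_type_one_error_rate_near_nominal(self):
        """Q independent of P: the slope t-test should reject ~5% of seeds."""
        rejections = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            P = rng.uniform(200, 400, size=18)
            Q = rng.normal(60, 15, size=18)
            if water_yield_coefficient(P, Q).p_value < 0.05:
                rejections += 1
        assert 0.03 < rejections / n_seeds < 0.07

    def test_detrending_removes_common_trend_confounding(self):
        """A shared linear trend inflates the raw slope; detrending removes it."""
        rng = np.random.default_rng(0)
        P = 300 + 5.0 * (YEARS - 1982) + rng.normal(0, 20, size=YEARS.size)
        Q = 60 + 2.0 * (YEARS - 1982) + rng.normal(0, 8, size=YEARS.size)
        raw = water_yield_coefficient(P, Q).slope
        det = water_yield_coefficient(P, Q, years=YEARS, detrended=True).slope
        assert abs(raw - det) > 0.05
        assert abs(det) < abs(raw)  # spurious trend association removed

    def test_zero_variance_precipitation_singular(self):
        with pytest.raises(fa.SingularDesignError):
            water_yield_coefficient(np.full(10, 300.0), RNG.normal(60, 5, size=10))


class TestPartialWYC:
    def test_recovers_exact_coefficients(self):
        P = RNG.uniform(200, 400, size=20)
        T = RNG.normal(5, 1, size=20)
        assert partial_wyc(P, T, 0.3 * P).slope == pytest.approx(0.3, abs=1e-10)
        assert partial_wyc(P, T, 0.3 * P - 2.0 * T).slope == pytest.approx(0.3, abs=1e-10)

    def test_frisch_waugh_residual_regression_oracle(self):
        rng = np.random.default_rng(7)
        P = rng.uniform(200, 400, size=24)
        T = 0.01 * P + rng.normal(0, 1, size=24)  # correlated regressors
        Q = 0.25 * P - 3.0 * T + rng.normal(0, 5, size=24)
        full = partial_wyc(P, T, Q).slope
        # residualize P and Q on (1, T), regress residual on residual
        for_t = np.column_stack([np.ones(T.size), T])
        proj = for_t @ np.linalg.lstsq(for_t, np.column_stack([P, Q]), rcond=None)[0]
        rP, rQ = P - proj[:, 0], Q - proj[:, 1]
        assert full == pytest.approx(float(rP @ rQ / (rP @ rP)), abs=1e-10)

    def test_orthogonal_temperature_matches_simple_slope(self):
        rng = np.random.default_rng(9)
        P = rng.uniform(200, 400, size=30)
        T = rng.normal(0, 1, size=30)
        # orthogonalize T against (1, P) in sample
        X = np.column_stack([np.ones(P.size), P])
        T = T - X @ np.linalg.lstsq(X, T, rcond=None)[0]
        Q = rng.normal(60, 10, size=30)
        simple = water_yield_coefficient(P, Q).slope
        assert partial_wyc(P, T, Q).slope == pytest.approx(simple, abs=1e-8)

    def test_collinear_regressors_singular(self):
        P = RNG.uniform(200, 400, size=15)
        with pytest.raises(fa.SingularDesignError):
            partial_wyc(P, 2.0 * P, RNG.normal(size=15))


class TestCompareWYC:
    @staticmethod
    def _periods(seed=0, slope_pre=0.5, slope_post=0.2, noise=0.0):
        rng = np.random.default_rng(seed)
        years_pre, years_post = np.arange(1982, 2000), np.arange(2000, 2013)
        P1 = rng.uniform(200, 400, size=years_pre.size)
        P2 = rng.uniform(250, 450, size=years_post.size)
        Q1 = slope_pre * P1 + rng.normal(0, noise, size=P1.size)
        Q2 = slope_post * P2 + rng.normal(0, noise, size=P2.size)
        return (years_pre, P1, Q1), (years_post, P2, Q2)

    def test_identical_periods_give_zero_difference(self):
        pre, _ = self._periods(noise=5.0)
        cmp = compare_wyc(pre, pre)
        assert cmp.difference == pytest.approx(0.0, abs=1e-10)

    def test_noise_free_slope_difference(self):
        pre, post = self._periods()
        cmp = compare_wyc(pre, post)
        assert cmp.difference == pytest.approx(-0.3, abs=1e-10)
        assert cmp.p_value < 1e-10

    def test_difference_equals_independent_slopes(self):
        pre, post = self._periods(seed=3, noise=8.0)
        cmp = compare_wyc(pre, post)
        s1 = water_yield_coefficient(pre[1], pre[2]).slope
        s2 = water_yield_coefficient(post[1], post[2]).slope
        assert cmp.difference == pytest.approx(s2 - s1, abs=1e-10)
        assert cmp.slope_pre == pytest.approx(s1, abs=1e-10)
        assert cmp.slope_post == pytest.approx(s2, abs=1e-10)
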