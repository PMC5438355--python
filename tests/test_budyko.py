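"""Budyko curve, omega calibration and the ET decomposition."""

import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import flowattrib as fa
from flowattrib.budyko import bootstrap_omega, budyko_et, decompose_et, fit_omega


def grid_search_omega(P, ETp, ET, coarse=1e-2, fine=1e-5):
    """Independent two-stage grid-search oracle over (0.1, 20)."""

    def rss(w):
        r = ET - budyko_et(P, ETp, w)
        return float(r @ r)

    coarse_grid = np.arange(0.1 + coarse, 20.0, coarse)
    best = coarse_grid[np.argmin([rss(w) for w in coarse_grid])]
    fine_grid = np.arange(best - coarse, best + coarse, fine)
    fine_grid = fine_grid[(fine_grid > 0.1) & (fine_grid < 20.0)]
    return fine_grid[np.argmin([rss(w) for w in fine_grid])]


class TestBudykoET:
    def test_equal_supply_and_demand(self):
        # P = ETp = 100, omega = 2: ET = 100 * 2^(-1/2)
        assert budyko_et(100.0, 100.0, 2.0) == pytest.approx(100.0 * 2 ** -0.5, rel=1e-12)

    def test_large_omega_limit_is_min(self):
        assert budyko_et(80.0, 200.0, 1e4) == pytest.approx(80.0, rel=1e-3)
        assert budyko_et(500.0, 120.0, 1e4) == pytest.approx(120.0, rel=1e-3)

    def test_monotone_in_omega(self):
        P, ETp = np.meshgrid(np.linspace(50, 500, 8), np.linspace(50, 500, 8))
        omegas = [0.5, 1.0, 2.0, 3.0, 5.0]
        ets = [budyko_et(P, ETp, w) for w in omegas]
        for lower, higher in zip(ets, ets[1:]):
            assert np.all(higher > lower)

    @given(
        st.floats(10.0, 1000.0),
        st.floats(10.0, 1000.0),
        st.floats(0.2, 10.0),
        st.floats(0.01, 100.0),
    )
    def test_bounds_and_scale_invariance(self, P, ETp, omega, c):
        et = budyko_et(P, ETp, omega)
        assert 0.0 < et < min(P, ETp)
        assert budyko_et(c * P, c * ETp, omega) == pytest.approx(c * et, rel=1e-10)

    @pytest.mark.parametrize("bad", [(0.0, 100.0, 2.0), (100.0, -1.0, 2.0), (100.0, 100.0, 0.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(fa.DomainError):
            budyko_et(*bad)


class TestFitOmega:
    @staticmethod
    def _noise_free(omega, seed=0, n=18):
        rng = np.random.default_rng(seed)
        P = rng.uniform(150, 450, size=n)
        ETp = rng.uniform(250, 500, size=n)
        return P, ETp, budyko_et(P, ETp, omega)

    def test_recovers_known_omega(self):
        P, ETp, ET = self._noise_free(2.6)
        fit = fit_omega((P, ETp, ET))
        assert fit.converged
        assert fit.omega == pytest.approx(2.6, abs=1e-4)
        assert fit.omega == pytest.approx(grid_search_omega(P, ETp, ET), abs=1e-4)

    def test_infeasible_target_hits_bound_with_warning(self):
        P = np.full(6, 100.0)
        ETp = np.full(6, 200.0)
        ET = np.full(6, 120.0)  # >= min(P, ETp): unreachable by the curve
        with pytest.warns(UserWarning, match="did not converge"):
            fit = fit_omega((P, ETp, ET))
        assert not fit.converged
        assert fit.omega > 19.9

    def test_invariant_under_year_reordering(self, default_run):
        series, _ = default_run
        pre = series.period(1982, 1999)
        fit = fit_omega(pre)
        perm = np.random.default_rng(1).permutation(len(pre))
        fit_perm = fit_omega((pre.P[perm], pre.ETp[perm], pre.ET[perm]))
        assert fit_perm.omega == pytest.approx(fit.omega, abs=1e-8)

    def test_requires_three_complete_years(self):
        with pytest.raises(fa.DataError):
            fit_omega((np.array([100.0, 200.0]), np.array([300.0, 300.0]), np.array([80.0, 90.0])))
        with pytest.raises(fa.DataError, match="complete"):
            fit_omega((np.array([100.0, 200.0, np.nan]), np.full(3, 300.0), np.full(3, 80.0)))


class TestBootstrapOmega:
    def test_degenerate_full_subsample_has_zero_spread(self, default_run):
        series, _ = default_run
        pre = series.period(1982, 1999)
        boot = bootstrap_omega(pre, n_draws=20, subsample_size=len(pre), seed=0)
        assert boot.omega_sd == pytest.approx(0.0, abs=1e-10)
        assert boot.omega_mean == pytest.approx(boot.omega, abs=1e-8)

    def test_noise_free_draws_all_recover_truth(self):
        P, ETp, ET = TestFitOmega._noise_free(2.3, seed=5)
        boot = bootstrap_omega((P, ETp, ET), n_draws=40, subsample_size=12, seed=1)
        assert boot.bootstrap_omegas.size == 40
        np.testing.assert_allclose(boot.bootstrap_omegas, 2.3, atol=1e-4)
        assert boot.omega_sd < 1e-5
        assert boot.n_failed_draws == 0

    def test_seed_reproducibility(self, default_run):
        series, _ = default_run
        pre = series.period(1982, 1999)
        a = bootstrap_omega(pre, n_draws=30, subsample_size=12, seed=9)
        b = bootstrap_omega(pre, n_draws=30, subsample_size=12, seed=9)
        np.testing.assert_array_equal(a.bootstrap_omegas, b.bootstrap_omegas)

    def test_oversized_subsample_rejected(self, default_run):
        series, _ = default_run
        pre = series.period(1982, 1999)
        with pytest.raises(fa.DataError, match="subsample"):
            bootstrap_omega(pre, n_draws=5, subsample_size=len(pre) + 1, seed=0)


class TestDecomposeET:
    def test_null_case_no_change(self, periods):
        """Same climate distribution in both eras, same omega: deltas ~ 0."""
        params = fa.GeneratorParams(
            seed=2, delta_P=0.0, delta_ETp=0.0, omega_post=2.0,
            sigma_ET_noise=0.0, sigma_S=0.0,
        )
        series, _ = fa.generate_catchment(params)
        d = decompose_et(series, periods, omega_ref=2.0)
        assert d.dET_veg == pytest.approx(0.0, abs=1e-9)
        assert abs(d.dET_tot) < 15.0  # only sampling noise between eras

    def test_noise_free_ground_truth_recovery(self, noisefree_run, periods):
        series, truth = noisefree_run
        fit = fit_omega(series.period(1982, 1999))
        d = decompose_et(series, periods, fit.omega)
        assert d.dET_veg == pytest.approx(truth.true_dET_veg, rel=0.05)

    def test_additivity_is_exact(self, default_run, periods):
        series, _ = default_run
        d = decompose_et(series, periods, omega_ref=2.0)
        assert d.dET_tot == d.dET_clim + d.dET_veg

    def test_yearly_vs_period_mean_flag(self, default_run, periods):
        series, _ = default_run
        yearly = decompose_et(series, periods, 2.0, yearly=True)
        bulk = decompose_et(series, periods, 2.0, yearly=False)
        assert yearly.dET_veg != bulk.dET_veg  # Jensen gap is nonzero
        assert abs(yearly.dET_veg - bulk.dET_veg) < 5.0  # ... but small
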