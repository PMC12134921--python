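"""State-space model tests: exact Gaussian filtering oracle,
causality, degenerate cases and MCMC behaviour."""

import numpy as np
import pytest
from scipy import stats

from conftest import gaussian_filter_oracle, simulate_dlm_series
from exalarm.cohort import LongitudinalSeries
from exalarm.dlm import (DLMParams, DLMPriors, MCMCConfig, filter_cohort,
                         filter_loglik, fit_dlm, kalman_filter)


def random_params(rng):
    return DLMParams(
        V=0.01 + 0.03 * rng.random(),
        W_mu=0.0005 + 0.004 * rng.random(),
        W_s=0.001 + 0.008 * rng.random(),
        W_b=0.002 + 0.01 * rng.random(),
        phi=0.2 + 0.6 * rng.random(),
    )


class TestKalmanOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_filtered_means_match_joint_gaussian_conditioning(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        batch = np.array([0, 0, 0, 1, 1, 1, 2, 2])
        params = random_params(rng)
        y = 1.0 + 0.3 * rng.standard_normal(n)
        if seed % 2:
            y[3] = np.nan
        m0 = np.array([1.0, 0.0, 0.0])
        C0 = np.diag([0.5, 0.2, 1e-12])
        ser = LongitudinalSeries("P", "M", np.arange(n), y, batch)
        fs = kalman_filter(ser, params, m0=m0, C0=C0)
        for t in range(n):
            causal_y = np.where(np.arange(n) <= t, y, np.nan)
            om, _ = gaussian_filter_oracle(causal_y, batch, params, m0, C0)
            assert fs.filtered_value[t] == pytest.approx(om[t, 0] + om[t, 1],
                                                         abs=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_loglik_matches_multivariate_normal_density(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 9
        batch = np.arange(n) // 4
        params = random_params(rng)
        y = rng.standard_normal(n)
        if seed % 2:
            y[5] = np.nan
        m0 = np.array([0.0, 0.0, 0.0])
        C0 = np.diag([1.0, 0.3, 1e-12])
        ser = LongitudinalSeries("P", "M", np.arange(n), y, batch)
        _, oll = gaussian_filter_oracle(y, batch, params, m0, C0)
        assert filter_loglik(ser, params, m0, C0) == pytest.approx(oll, abs=1e-8)


class TestKalmanFilter:
    def test_degenerate_state_stays_at_known_level(self):
        params = DLMParams(V=0.01, W_mu=0.0, W_s=0.0, W_b=0.0, phi=0.5)
        rng = np.random.default_rng(0)
        y = 2.0 + rng.standard_normal(30) * 0.1
        ser = LongitudinalSeries("P", "M", np.arange(30), y, np.zeros(30, int))
        fs = kalman_filter(ser, params, m0=np.array([2.0, 0.0, 0.0]),
                           C0=np.zeros((3, 3)))
        assert np.allclose(fs.filtered_value, 2.0)

    def test_missing_day_uses_prediction_and_inflates_variance(self):
        params = DLMParams(V=0.01, W_mu=0.001, W_s=0.002, W_b=0.0, phi=0.6)
        y = np.array([1.0, 1.1, np.nan, 0.9, 1.0])
        ser = LongitudinalSeries("P", "M", np.arange(5), y, np.zeros(5, int))
        fs = kalman_filter(ser, params, m0=np.array([1.0, 0, 0]),
                           C0=np.diag([0.2, 0.05, 0.0]))
        prefix = kalman_filter(ser.truncate(1), params,
                               m0=np.array([1.0, 0, 0]),
                               C0=np.diag([0.2, 0.05, 0.0]))
        # prediction for the missing day propagates day-1's posterior
        assert not fs.observed[2]
        assert fs.filtered_value[2] == pytest.approx(
            prefix.filtered_value[1] * 1.0 + 0.0, rel=0.2)
        assert fs.filtered_sd[2] > prefix.filtered_sd[1]

    def test_causality_prefix_invariance(self):
        rng = np.random.default_rng(5)
        params = random_params(rng)
        ser = simulate_dlm_series(params, 40, seed=5, missing_prob=0.15)
        if np.isnan(ser.values[0]):
            ser.values[0] = 1.5
        full = kalman_filter(ser, params)
        for t in (0, 7, 20, 39):
            pre = kalman_filter(ser.truncate(t), params)
            assert np.allclose(full.filtered_value[:t + 1], pre.filtered_value,
                               atol=1e-10)

    def test_filtering_reduces_variance_of_pure_noise(self):
        rng = np.random.default_rng(3)
        y = 1.0 + 0.2 * rng.standard_normal(300)
        ser = LongitudinalSeries("P", "M", np.arange(300), y,
                                 np.zeros(300, int))
        params = DLMParams(V=0.04, W_mu=1e-5, W_s=1e-4, W_b=0.0, phi=0.5)
        fs = kalman_filter(ser, params)
        assert fs.filtered_value[50:].std() < y[50:].std()

    def test_filter_cohort_composition_and_missing_key(self):
        rng = np.random.default_rng(1)
        params = random_params(rng)
        ser = simulate_dlm_series(params, 30, seed=2, missing_prob=0.0)
        out = filter_cohort([ser], {("P0", "M"): params})
        direct = kalman_filter(ser, params)
        assert np.array_equal(out[("P0", "M")].filtered_value,
                              direct.filtered_value)
        with pytest.raises(KeyError):
            filter_cohort([ser], {})


class TestFitDlm:
    def test_determinism_identical_draws(self):
        params = DLMParams(V=0.0016, W_mu=4e-6, W_s=8e-4, W_b=0.0025, phi=0.7)
        ser = simulate_dlm_series(params, 120, seed=3)
        cfg = MCMCConfig(iterations=400, burn_in=100, thin=2, seed=11)
        a = fit_dlm(ser, mcmc=cfg)
        b = fit_dlm(ser, mcmc=cfg)
        assert np.array_equal(a.params, b.params)
        assert np.array_equal(a.imputed, b.imputed)

    def test_too_few_observations_rejected(self):
        y = np.full(20, np.nan)
        y[:5] = 1.0
        ser = LongitudinalSeries("P", "M", np.arange(20), y, np.zeros(20, int))
        with pytest.raises(ValueError, match="non-missing"):
            fit_dlm(ser)

    def test_no_batch_changes_leaves_batch_variance_at_prior(self):
        params = DLMParams(V=0.0016, W_mu=4e-6, W_s=8e-4, W_b=0.0025, phi=0.7)
        ser = simulate_dlm_series(params, 250, seed=4, batch_length=1000,
                                  missing_prob=0.0)
        priors = DLMPriors()
        fit = fit_dlm(ser, priors, MCMCConfig(iterations=3000, burn_in=500,
                                              seed=2, store_states=False))
        draws = fit.params[:, 3]
        prior = stats.invgamma(priors.wb_shape, scale=priors.wb_scale)
        # heavy-tailed, so compare quantiles rather than moments
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(draws, q) == pytest.approx(prior.ppf(q), rel=0.2)

    def test_posterior_v_tracks_truth_on_noise_dominated_series(self):
        # nearly static level: V is essentially the sample variance
        params = DLMParams(V=0.0025, W_mu=1e-8, W_s=1e-8, W_b=0.0, phi=0.3)
        ser = simulate_dlm_series(params, 300, seed=8, batch_length=1000,
                                  missing_prob=0.0)
        fit = fit_dlm(ser, mcmc=MCMCConfig(iterations=2000, burn_in=500,
                                           seed=3, store_states=False))
        assert fit.posterior_mean().V == pytest.approx(0.0025, rel=0.35)

    def test_imputed_draws_cover_missing_positions(self):
        params = DLMParams(V=0.0016, W_mu=4e-6, W_s=8e-4, W_b=0.0025, phi=0.7)
        ser = simulate_dlm_series(params, 100, seed=9, missing_prob=0.2)
        fit = fit_dlm(ser, mcmc=MCMCConfig(iterations=300, burn_in=100, seed=1))
        assert fit.imputed.shape[1] == int(np.isnan(ser.values).sum())
        assert np.array_equal(fit.missing_index,
                              np.flatnonzero(np.isnan(ser.values)))
        assert np.all(np.isfinite(fit.imputed))
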