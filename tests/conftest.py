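import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from exalarm.cohort import CohortConfig, LongitudinalSeries, generate_cohort
from exalarm.dlm import DLMParams


@pytest.fixture(scope="session")
def small_cohort():
    """10-patient cohort with events, shared across read-only tests."""
    cfg = CohortConfig(n_patients=10, n_days=160, exac_hazard=0.008, seed=42)
    series, events = generate_cohort(cfg)
    return cfg, series, events


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def simulate_dlm_series(params: DLMParams, n: int, seed: int,
                        batch_length: int = 28, missing_prob: float = 0.1,
                        level0: float = 1.5) -> LongitudinalSeries:
    """Simulate data exactly from the state-space model (test oracle input)."""
    r = np.random.default_rng(seed)
    mu = level0 + np.cumsum(np.sqrt(params.W_mu) * r.standard_normal(n))
    s = np.zeros(n)
    for t in range(1, n):
        s[t] = params.phi * s[t - 1] + np.sqrt(params.W_s) * r.standard_normal()
    batch = np.arange(n) // batch_length
    n_b = int(batch[-1]) + 1
    offs = np.concatenate([[0.0], np.cumsum(np.sqrt(params.W_b) * r.standard_normal(n_b - 1))]) \
        if n_b > 1 else np.zeros(1)
    y = mu + s + offs[batch] + np.sqrt(params.V) * r.standard_normal(n)
    if missing_prob > 0:
        y[r.random(n) < missing_prob] = np.nan
    return LongitudinalSeries("P0", "M", np.arange(n), y, batch)


def gaussian_filter_oracle(y, batch, params: DLMParams, m0, C0):
    """Exact filtered state means and observed-data log-likelihood by
    joint multivariate-normal conditioning (brute force, n small)."""
    from scipy.stats import multivariate_normal

    n = len(y)
    g = np.diag([1.0, params.phi, 1.0])

    def W(t):
        wb = params.W_b if (t > 0 and batch[t] != batch[t - 1]) else 0.0
        return np.diag([params.W_mu, params.W_s, wb])

    means = np.zeros((n, 3))
    means[0] = m0
    margs = [np.asarray(C0, float)]
    for t in range(1, n):
        margs.append(g @ margs[-1] @ g.T + W(t))
        means[t] = g @ means[t - 1]
    big = np.zeros((3 * n, 3 * n))
    for t in range(n):
        big[3 * t:3 * t + 3, 3 * t:3 * t + 3] = margs[t]
        C = margs[t]
        for u in range(t + 1, n):
            C = C @ g.T
            big[3 * t:3 * t + 3, 3 * u:3 * u + 3] = C
            big[3 * u:3 * u + 3, 3 * t:3 * t + 3] = C.T
    H = np.ones(3)
    obs_idx = [t for t in range(n) if np.isfinite(y[t])]
    Hbig = np.zeros((len(obs_idx), 3 * n))
    for i, t in enumerate(obs_idx):
        Hbig[i, 3 * t:3 * t + 3] = H
    Syy = Hbig @ big @ Hbig.T + params.V * np.eye(len(obs_idx))
    Sxy = big @ Hbig.T
    mu_y = Hbig @ means.flatten()
    yobs = np.array([y[t] for t in obs_idx])
    cond_mean = means.flatten() + Sxy @ np.linalg.solve(Syy, yobs - mu_y)
    ll = multivariate_normal(mean=mu_y, cov=Syy).logpdf(yobs)
    return cond_mean.reshape(n, 3), float(ll)
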