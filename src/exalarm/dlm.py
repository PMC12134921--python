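"""Non-homogeneous dynamic linear model for daily biomarker series.

Each biomarker series (log10 scale) is modelled by a Gaussian
state-space model with state (mu_t, s_t, b_t):

    y_t   = mu_t + s_t + b_t + eps_t,      eps_t ~ N(0, V)
    mu_t  = mu_{t-1} + w1_t,               w1_t ~ N(0, W_mu)   (slow drift)
    s_t   = phi * s_{t-1} + w2_t,          w2_t ~ N(0, W_s)    (AR(1) day-to-day)
    b_t   = b_{t-1} + w3_t * 1[batch change at t], w3 ~ N(0, W_b)

so the four variance parameters are (V, W_mu, W_s, W_b) plus the
autoregressive coefficient phi.  The batch component is constant
within a device batch and steps only at batch boundaries.

Fitting is Bayesian: a Gibbs sampler alternates forward-filtering
backward-sampling of the state path, conjugate inverse-gamma updates
of the variances, a Metropolis step for phi, and imputation of
missing observations from their conditional normal (missingness is
assumed non-informative).  The Kalman filter then produces strictly
causal per-day filtered values E[mu_t + s_t | y_{1:t}] at the
posterior-mean parameters; the batch component is excluded from the
filtered value by default, treating batch steps as device artefact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .cohort import LongitudinalSeries

__all__ = [
    "DLMParams",
    "DLMPriors",
    "MCMCConfig",
    "PosteriorDraws",
    "FilteredSeries",
    "fit_dlm",
    "kalman_filter",
    "filter_loglik",
    "filter_cohort",
]


@dataclass(frozen=True)
class DLMParams:
    V: float        # observation variance, log10 units^2
    W_mu: float     # drift innovation variance
    W_s: float      # AR(1) innovation variance
    W_b: float      # batch-step variance
    phi: float      # AR(1) coefficient

    def __post_init__(self) -> None:
        for name in ("V", "W_mu", "W_s", "W_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not abs(self.phi) < 1:
            raise ValueError("phi must satisfy |phi| < 1")


def _ig_from_mean_sd(mean_sd: float, shape: float = 2.0) -> tuple[float, float]:
    """Inverse-gamma (shape, scale) whose mean equals ``mean_sd**2``.

    With shape a and scale c, E[sigma^2] = c / (a - 1).
    """
    return shape, mean_sd**2 * (shape - 1.0)


@dataclass(frozen=True)
class DLMPriors:
    """Vague priors for the four variances and phi.

    Defaults encode the prior judgement that day-to-day variation is
    roughly +/-10% of the local level, i.e. sd ~ 0.04 on the log10
    scale: the observation-noise sd is centred at 0.04, and the AR(1)
    innovation sd at 0.04 * sqrt(1 - 0.7^2) ~ 0.028 so that the
    marginal (stationary) AR fluctuation matches the same +/-10%
    judgement at a typical persistence of 0.7.  The slow drift is an
    order of magnitude smaller per day.  phi is uniform on (0, 0.99).
    """

    v_shape: float = 2.0
    v_scale: float = 0.04**2
    wmu_shape: float = 2.0
    wmu_scale: float = 0.01**2
    ws_shape: float = 2.0
    ws_scale: float = 0.028**2
    wb_shape: float = 2.0
    wb_scale: float = 0.05**2
    phi_low: float = 0.0
    phi_high: float = 0.99

    def __post_init__(self) -> None:
        for name in ("v_shape", "v_scale", "wmu_shape", "wmu_scale",
                     "ws_shape", "ws_scale", "wb_shape", "wb_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (-1 < self.phi_low < self.phi_high < 1):
            raise ValueError("phi bounds must satisfy -1 < low < high < 1")


@dataclass(frozen=True)
class MCMCConfig:
    iterations: int = 4000
    burn_in: int = 1000
    thin: int = 2
    seed: int = 0
    store_states: bool = True

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Kept MCMC draws of parameters, state paths and imputed data."""

    params: np.ndarray            # (n_keep, 5): V, W_mu, W_s, W_b, phi
    states: np.ndarray | None     # (n_keep, n_days, 3) or None
    imputed: np.ndarray | None    # (n_keep, n_missing) imputed y draws
    missing_index: np.ndarray     # day positions of the imputed values
    config: MCMCConfig

    def posterior_mean(self) -> DLMParams:
        m = self.params.mean(axis=0)
        return DLMParams(V=float(m[0]), W_mu=float(m[1]), W_s=float(m[2]),
                         W_b=float(m[3]), phi=float(m[4]))


@dataclass
class FilteredSeries:
    """Strictly causal filtered values: E[mu_t + s_t | y_{1:t}]."""

    patient_id: str
    marker: str
    days: np.ndarray
    filtered_value: np.ndarray
    filtered_sd: np.ndarray
    observed: np.ndarray  # bool: was that day's observation present


# ---------------------------------------------------------------------------
# Gibbs sampler kernel (jitted).  State propagation uses the diagonal
# transition G = diag(1, phi, 1) so 3x3 algebra is written explicitly.
# ---------------------------------------------------------------------------

_JITTER = 1e-12


@njit(cache=False)
def _ffbs(y, wchange, V, W_mu, W_s, W_b, phi, m0, C0):  # pragma: no cover - jitted
    n = y.shape[0]
    ms = np.zeros((n, 3))
    Cs = np.zeros((n, 3, 3))
    g = np.array([1.0, phi, 1.0])
    for t in range(n):
        if t == 0:
            a = m0.copy()
            R = C0.copy()
        else:
            a = g * ms[t - 1]
            R = np.empty((3, 3))
            for i in range(3):
                for j in range(3):
                    R[i, j] = g[i] * g[j] * Cs[t - 1, i, j]
            R[0, 0] += W_mu
            R[1, 1] += W_s
            if wchange[t]:
                R[2, 2] += W_b
        for i in range(3):
            R[i, i] += _JITTER
        f = a[0] + a[1] + a[2]
        rsum = np.empty(3)
        for i in range(3):
            rsum[i] = R[i, 0] + R[i, 1] + R[i, 2]
        q = rsum[0] + rsum[1] + rsum[2] + V
        K = rsum / q
        e = y[t] - f
        for i in range(3):
            ms[t, i] = a[i] + K[i] * e
            for j in range(3):
                Cs[t, i, j] = R[i, j] - q * K[i] * K[j]
    # backward sampling
    x = np.zeros((n, 3))
    C_last = Cs[n - 1] + np.eye(3) * _JITTER
    L = np.linalg.cholesky(C_last)
    z = np.empty(3)
    for i in range(3):
        z[i] = np.random.standard_normal()
    x[n - 1] = ms[n - 1] + L @ z
    for t in range(n - 2, -1, -1):
        a_next = g * ms[t]
        R = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                R[i, j] = g[i] * g[j] * Cs[t, i, j]
        R[0, 0] += W_mu
        R[1, 1] += W_s
        if wchange[t + 1]:
            R[2, 2] += W_b
        for i in range(3):
            R[i, i] += _JITTER
        Rinv = np.linalg.inv(R)
        # B = C_t G' Rinv  (G diagonal)
        CG = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                CG[i, j] = Cs[t, i, j] * g[j]
        B = CG @ Rinv
        diff = x[t + 1] - a_next
        h = ms[t] + B @ diff
        H = Cs[t] - B @ CG.T
        H = 0.5 * (H + H.T) + np.eye(3) * _JITTER
        L = np.linalg.cholesky(H)
        for i in range(3):
            z[i] = np.random.standard_normal()
        x[t] = h + L @ z
    return x


@njit(cache=False)
def _gibbs_kernel(y_obs, miss, wchange, n_iter, burn, thin,  # pragma: no cover - jitted
                  a_v, c_v, a_wmu, c_wmu, a_ws, c_ws, a_wb, c_wb,
                  phi_lo, phi_hi, seed, store_states):
    np.random.seed(seed)
    n = y_obs.shape[0]
    n_keep = (n_iter - burn + thin - 1) // thin
    n_miss = int(miss.sum())
    params_out = np.zeros((n_keep, 5))
    states_out = np.zeros((n_keep, n, 3)) if store_states else np.zeros((1, 1, 3))
    imputed_out = np.zeros((n_keep, n_miss))

    # initial values: prior means
    V = c_v / (a_v - 1.0) if a_v > 1.0 else c_v
    W_mu = c_wmu / (a_wmu - 1.0) if a_wmu > 1.0 else c_wmu
    W_s = c_ws / (a_ws - 1.0) if a_ws > 1.0 else c_ws
    W_b = c_wb / (a_wb - 1.0) if a_wb > 1.0 else c_wb
    phi = 0.5 * (phi_lo + phi_hi)

    obs_sum = 0.0
    obs_n = 0
    for t in range(n):
        if not miss[t]:
            obs_sum += y_obs[t]
            obs_n += 1
    ybar = obs_sum / obs_n
    y = y_obs.copy()
    for t in range(n):
        if miss[t]:
            y[t] = ybar

    m0 = np.array([ybar, 0.0, 0.0])
    n_changes = 0
    for t in range(1, n):
        if wchange[t]:
            n_changes += 1

    kept = 0
    for it in range(n_iter):
        C0 = np.zeros((3, 3))
        C0[0, 0] = 1.0
        C0[1, 1] = W_s / max(1.0 - phi * phi, 1e-6)
        C0[2, 2] = _JITTER
        x = _ffbs(y, wchange, V, W_mu, W_s, W_b, phi, m0, C0)

        # conjugate IG updates
        sse_v = 0.0
        for t in range(n):
            r = y[t] - x[t, 0] - x[t, 1] - x[t, 2]
            sse_v += r * r
        V = 1.0 / np.random.gamma(a_v + 0.5 * n, 1.0 / (c_v + 0.5 * sse_v))

        sse_mu = 0.0
        sse_s = 0.0
        sxx = 0.0
        sxy = 0.0
        for t in range(1, n):
            dmu = x[t, 0] - x[t - 1, 0]
            sse_mu += dmu * dmu
            ds = x[t, 1] - phi * x[t - 1, 1]
            sse_s += ds * ds
            sxx += x[t - 1, 1] * x[t - 1, 1]
            sxy += x[t - 1, 1] * x[t, 1]
        W_mu = 1.0 / np.random.gamma(a_wmu + 0.5 * (n - 1),
                                     1.0 / (c_wmu + 0.5 * sse_mu))
        W_s = 1.0 / np.random.gamma(a_ws + 0.5 * (n - 1),
                                    1.0 / (c_ws + 0.5 * sse_s))

        sse_b = 0.0
        for t in range(1, n):
            if wchange[t]:
                db = x[t, 2] - x[t - 1, 2]
                sse_b += db * db
        W_b = 1.0 / np.random.gamma(a_wb + 0.5 * n_changes,
                                    1.0 / (c_wb + 0.5 * sse_b))

        # Metropolis random-walk update for phi
        prop = phi + 0.1 * np.random.standard_normal()
        if phi_lo < prop < phi_hi:
            sse_prop = 0.0
            for t in range(1, n):
                ds = x[t, 1] - prop * x[t - 1, 1]
                sse_prop += ds * ds
            log_ratio = (sse_s - sse_prop) / (2.0 * W_s)
            if np.log(np.random.random()) < log_ratio:
                phi = prop
                sse_s = sse_prop

        # impute missing observations
        for t in range(n):
            if miss[t]:
                y[t] = (x[t, 0] + x[t, 1] + x[t, 2]
                        + np.sqrt(V) * np.random.standard_normal())

        if it >= burn and (it - burn) % thin == 0:
            params_out[kept, 0] = V
            params_out[kept, 1] = W_mu
            params_out[kept, 2] = W_s
            params_out[kept, 3] = W_b
            params_out[kept, 4] = phi
            if store_states:
                states_out[kept] = x
            k = 0
            for t in range(n):
                if miss[t]:
                    imputed_out[kept, k] = y[t]
                    k += 1
            kept += 1
    return params_out, states_out, imputed_out


def fit_dlm(series: LongitudinalSeries, priors: DLMPriors | None = None,
            mcmc: MCMCConfig | None = None) -> PosteriorDraws:
    """Fit the DLM to one biomarker series by Gibbs sampling.

    Missing observations are treated as unknowns and imputed at each
    iteration; identical (seed, data, priors) produce identical draw
    sequences.
    """
    priors = priors or DLMPriors()
    mcmc = mcmc or MCMCConfig()
    values = np.asarray(series.values, dtype=float)
    miss = np.isnan(values)
    n_obs = int((~miss).sum())
    if n_obs < 10:
        raise ValueError(f"need >= 10 non-missing observations, got {n_obs}")
    if not np.all(np.isfinite(values[~miss])):
        raise ValueError("non-finite observation values")
    wchange = np.zeros(len(values), dtype=np.bool_)
    wchange[1:] = np.diff(series.batch_ids) != 0

    y = values.copy()
    y[miss] = 0.0  # placeholder; kernel overwrites with the running mean
    params, states, imputed = _gibbs_kernel(
        y, miss, wchange,
        mcmc.iterations, mcmc.burn_in, mcmc.thin,
        priors.v_shape, priors.v_scale,
        priors.wmu_shape, priors.wmu_scale,
        priors.ws_shape, priors.ws_scale,
        priors.wb_shape, priors.wb_scale,
        priors.phi_low, priors.phi_high,
        mcmc.seed, mcmc.store_states,
    )
    return PosteriorDraws(
        params=params,
        states=states if mcmc.store_states else None,
        imputed=imputed,
        missing_index=np.flatnonzero(miss),
        config=mcmc,
    )


# ---------------------------------------------------------------------------
# Deterministic Kalman filter (pure numpy; independent of the sampler)
# ---------------------------------------------------------------------------


def _default_init(series: LongitudinalSeries, params: DLMParams):
    values = np.asarray(series.values, dtype=float)
    finite = values[np.isfinite(values)]
    level0 = float(finite[0]) if len(finite) else 0.0
    s_var = params.W_s / max(1.0 - params.phi**2, 1e-6)
    m0 = np.array([level0, 0.0, 0.0])
    C0 = np.diag([1.0, s_var, 0.0])
    return m0, C0


def _filter_core(series: LongitudinalSeries, params: DLMParams,
                 m0: np.ndarray, C0: np.ndarray):
    """Forward Kalman recursion.

    Returns per-day posterior means/covariances, one-step prediction
    means/variances, and the log-likelihood contributions of observed
    days (prediction-error decomposition).
    """
    y = np.asarray(series.values, dtype=float)
    n = len(y)
    wchange = np.zeros(n, dtype=bool)
    wchange[1:] = np.diff(series.batch_ids) != 0
    g = np.array([1.0, params.phi, 1.0])
    H = np.ones(3)
    ms = np.zeros((n, 3))
    Cs = np.zeros((n, 3, 3))
    loglik = 0.0
    m, C = m0.astype(float).copy(), C0.astype(float).copy()
    for t in range(n):
        if t > 0:
            a = g * m
            R = (g[:, None] * g[None, :]) * C
            R = R + np.diag([params.W_mu, params.W_s,
                             params.W_b if wchange[t] else 0.0])
        else:
            a, R = m, C
        observed = np.isfinite(y[t])
        if observed:
            f = float(H @ a)
            q = float(H @ R @ H + params.V)
            K = (R @ H) / q
            e = y[t] - f
            m = a + K * e
            C = R - q * np.outer(K, K)
            loglik += -0.5 * (np.log(2 * np.pi * q) + e * e / q)
        else:
            m, C = a, R
        ms[t] = m
        Cs[t] = C
    return ms, Cs, loglik


def kalman_filter(series: LongitudinalSeries, params: DLMParams,
                  include_batch: bool = False,
                  m0: np.ndarray | None = None,
                  C0: np.ndarray | None = None) -> FilteredSeries:
    """Strictly causal filtered values for one series.

    The filtered value on day t is E[mu_t + s_t | y_{1:t}] (batch
    component excluded unless ``include_batch``); on missing days the
    update is skipped so the value is the one-step prediction.  The
    default initial level prior is centred on the first available
    observation with variance 1 (log10 units^2).
    """
    if m0 is None or C0 is None:
        d0, D0 = _default_init(series, params)
        m0 = d0 if m0 is None else np.asarray(m0, float)
        C0 = D0 if C0 is None else np.asarray(C0, float)
    ms, Cs, _ = _filter_core(series, params, np.asarray(m0, float),
                             np.asarray(C0, float))
    h = np.array([1.0, 1.0, 1.0 if include_batch else 0.0])
    value = ms @ h
    var = np.einsum("i,tij,j->t", h, Cs, h)
    return FilteredSeries(
        patient_id=series.patient_id,
        marker=series.marker,
        days=np.asarray(series.days, int).copy(),
        filtered_value=value,
        filtered_sd=np.sqrt(np.maximum(var, 0.0)),
        observed=np.isfinite(np.asarray(series.values, float)),
    )


def filter_loglik(series: LongitudinalSeries, params: DLMParams,
                  m0: np.ndarray, C0: np.ndarray) -> float:
    """Gaussian log-likelihood of the observed data by the
    prediction-error decomposition of the Kalman filter."""
    _, _, ll = _filter_core(series, params, np.asarray(m0, float),
                            np.asarray(C0, float))
    return float(ll)


def filter_cohort(
    series_list: list[LongitudinalSeries],
    params_by_key: dict[tuple[str, str], DLMParams],
    include_batch: bool = False,
) -> dict[tuple[str, str], FilteredSeries]:
    """Apply the Kalman filter to every (patient, marker) series using
    fitted (e.g. posterior-mean) parameters."""
    out: dict[tuple[str, str], FilteredSeries] = {}
    for s in series_list:
        key = (s.patient_id, s.marker)
        if key not in params_by_key:
            raise KeyError(f"no fitted parameters for patient/marker {key}")
        out[key] = kalman_filter(s, params_by_key[key], include_batch)
    return out
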