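"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of daily home urine-biomarker
telemonitoring in COPD: per-patient log-scale baselines, slow drift,
step changes at test-device batch boundaries, AR(1) day-to-day
fluctuation, observation noise, non-informative missingness, a
pre-exacerbation rise in informative markers over a ~13-day lead-in,
and a 6-week post-exacerbation recovery decay.

All concentrations are generated on the log10 scale; linear-scale
values are ``10**x``.  A day-to-day standard deviation of 0.04 log10
units corresponds to roughly +/-10% multiplicative fluctuation around
the local level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CohortConfig",
    "LongitudinalSeries",
    "EventTable",
    "PairedSampleSet",
    "generate_cohort",
    "generate_paired_samples",
]

#: Stream tags for per-purpose substreams of the root seed.
_STREAM_EVENTS = 1
_STREAM_SERIES = 2
_STREAM_PAIRED = 3


def _rng(seed: int, *keys: int) -> np.random.Generator:
    """Derive an independent substream from (seed, keys).

    Uses ``np.random.SeedSequence([seed, *keys])`` so that streams for
    different patients/markers are independent and adding a patient
    does not perturb the draws of existing ones.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a 6-month daily home-testing study: ~180 study
    days, device batches replaced every 4 weeks, ~12% of daily tests
    missing, and a per-day exacerbation hazard giving roughly one
    event per two patients over the study.
    """

    n_patients: int = 30
    n_days: int = 180
    marker_names: tuple[str, ...] = ("NGAL", "TIMP1", "CRP", "FIB", "CC16")
    baseline_mean: float = 1.5      # log10 concentration units
    baseline_sd: float = 0.30       # between-patient spread
    drift_sd: float = 0.002         # per-day random-walk innovation sd
    ar_coef: float = 0.7
    ar_sd: float = 0.04             # stationary sd of the AR component (~ +/-10%)
    obs_sd: float = 0.04            # assay/observation noise
    batch_length: int = 28          # days per device batch
    batch_sd: float = 0.05          # step size at batch changes
    missing_prob: float = 0.12
    exac_hazard: float = 0.003      # per-day event probability
    lead_days: int = 13             # pre-exacerbation ramp span
    shift_magnitude: float = 0.10   # peak pre-event rise, log10 units
    recovery_days: int = 42         # 6-week recovery decay span
    informative_markers: tuple[str, ...] = ("NGAL", "TIMP1", "CRP")
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(name: str, why: str):
            return ValueError(f"invalid CohortConfig.{name}: {why}")

        if self.n_patients < 1:
            raise bad("n_patients", "must be >= 1")
        if self.n_days < 1:
            raise bad("n_days", "must be >= 1")
        if not self.marker_names:
            raise bad("marker_names", "must be non-empty")
        for name in ("baseline_sd", "drift_sd", "ar_sd", "obs_sd", "batch_sd"):
            if getattr(self, name) < 0:
                raise bad(name, "standard deviation must be >= 0")
        if not abs(self.ar_coef) < 1:
            raise bad("ar_coef", "must satisfy |ar_coef| < 1")
        for name in ("missing_prob", "exac_hazard"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise bad(name, "must be a probability in [0, 1]")
        if self.batch_length < 1:
            raise bad("batch_length", "must be >= 1")
        if self.lead_days < 1:
            raise bad("lead_days", "must be >= 1")
        if self.recovery_days < 0:
            raise bad("recovery_days", "must be >= 0")
        unknown = set(self.informative_markers) - set(self.marker_names)
        if unknown:
            raise bad("informative_markers", f"not in marker_names: {sorted(unknown)}")
        # Normalise list inputs to tuples so configs hash/compare cleanly.
        object.__setattr__(self, "marker_names", tuple(self.marker_names))
        object.__setattr__(self, "informative_markers", tuple(self.informative_markers))

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class LongitudinalSeries:
    """Daily log10 concentrations of one biomarker for one patient.

    ``values`` holds NaN on missing days; ``batch_ids`` is
    piecewise-constant and non-decreasing.
    """

    patient_id: str
    marker: str
    days: np.ndarray
    values: np.ndarray
    batch_ids: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.batch_ids = np.asarray(self.batch_ids, dtype=int)
        if not (np.diff(self.days) > 0).all():
            raise ValueError("days must be strictly increasing")
        if np.any(np.diff(self.batch_ids) < 0):
            raise ValueError("batch_ids must be non-decreasing")
        if not (len(self.days) == len(self.values) == len(self.batch_ids)):
            raise ValueError("days, values, batch_ids must be equal length")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def truncate(self, day: int) -> "LongitudinalSeries":
        """Prefix of the series up to and including ``day``."""
        keep = self.days <= day
        return LongitudinalSeries(
            self.patient_id, self.marker,
            self.days[keep], self.values[keep], self.batch_ids[keep],
        )


@dataclass
class EventTable:
    """Clinician-confirmed exacerbation days per patient."""

    events: dict[str, list[int]] = field(default_factory=dict)

    def days_for(self, patient_id: str) -> list[int]:
        return sorted(self.events.get(patient_id, []))

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.events.values())


@dataclass
class PairedSampleSet:
    """One stable and one exacerbation sample per patient, linear scale.

    ``stable`` and ``exacerbation`` are (n_patients, n_markers) arrays
    of positive concentrations, columns ordered as ``markers``.
    """

    markers: tuple[str, ...]
    patient_ids: list[str]
    stable: np.ndarray
    exacerbation: np.ndarray

    def __post_init__(self) -> None:
        if self.stable.shape != self.exacerbation.shape:
            raise ValueError("stable/exacerbation shapes differ")
        if np.any(self.stable <= 0) or np.any(self.exacerbation <= 0):
            raise ValueError("concentrations must be positive")


def _patient_events(cfg: CohortConfig, p: int) -> list[int]:
    """Draw exacerbation days with > recovery_days separation.

    After each event the hazard is suppressed for ``recovery_days``
    days, which guarantees the generator invariant that successive
    events are more than one recovery span apart.
    """
    rng = _rng(cfg.seed, _STREAM_EVENTS, p)
    u = rng.random(cfg.n_days)
    days: list[int] = []
    blocked_until = -1
    # earliest allowed event leaves a full lead-in before it
    for d in range(cfg.lead_days, cfg.n_days):
        if d <= blocked_until:
            continue
        if u[d] < cfg.exac_hazard:
            days.append(d)
            blocked_until = d + cfg.recovery_days
    return days


def _shift_profile(cfg: CohortConfig, events: list[int]) -> np.ndarray:
    """Additive log10 shift: linear ramp into each event, exponential
    decay (half-life recovery_days/4) after it."""
    shift = np.zeros(cfg.n_days)
    half_life = max(cfg.recovery_days / 4.0, 1e-9)
    decay = np.log(2.0) / half_life
    for ev in events:
        ramp_start = ev - cfg.lead_days
        for d in range(max(ramp_start, 0), min(ev + 1, cfg.n_days)):
            frac = (d - ramp_start) / cfg.lead_days
            shift[d] = max(shift[d], cfg.shift_magnitude * frac)
        for d in range(ev + 1, cfg.n_days):
            val = cfg.shift_magnitude * np.exp(-decay * (d - ev))
            if val < 1e-6:
                break
            shift[d] = max(shift[d], val)
    return shift


def generate_cohort(config: CohortConfig) -> tuple[list[LongitudinalSeries], EventTable]:
    """Simulate daily log10 biomarker series and an event table.

    Each series is baseline + drift random walk + batch offsets +
    AR(1) fluctuation + pre-exacerbation shift (informative markers
    only) + observation noise, with MCAR missingness.  Identical
    config (including seed) gives identical output.
    """
    cfg = config
    days = np.arange(cfg.n_days)
    batch_ids = days // cfg.batch_length
    event_table = EventTable()
    series: list[LongitudinalSeries] = []
    informative = set(cfg.informative_markers)

    for p in range(cfg.n_patients):
        pid = f"P{p:03d}"
        events = _patient_events(cfg, p)
        event_table.events[pid] = events
        shift = _shift_profile(cfg, events)
        for m, marker in enumerate(cfg.marker_names):
            rng = _rng(cfg.seed, _STREAM_SERIES, p, m)
            baseline = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal()
            drift = np.cumsum(cfg.drift_sd * rng.standard_normal(cfg.n_days))
            # batch offsets: new draw at each batch boundary, first batch = 0
            n_batches = int(batch_ids[-1]) + 1
            offsets = np.concatenate([[0.0], np.cumsum(cfg.batch_sd * rng.standard_normal(n_batches - 1))]) if n_batches > 1 else np.zeros(1)
            batch_component = offsets[batch_ids]
            # stationary AR(1); ar_sd is the marginal (stationary) sd, so the
            # innovation sd is ar_sd * sqrt(1 - ar_coef^2)
            s = np.empty(cfg.n_days)
            innov_sd = cfg.ar_sd * np.sqrt(1 - cfg.ar_coef**2)
            innov = innov_sd * rng.standard_normal(cfg.n_days)
            s[0] = cfg.ar_sd * rng.standard_normal()
            for t in range(1, cfg.n_days):
                s[t] = cfg.ar_coef * s[t - 1] + innov[t]
            noise = cfg.obs_sd * rng.standard_normal(cfg.n_days)
            y = baseline + drift + batch_component + s + noise
            if marker in informative:
                y = y + shift
            miss = rng.random(cfg.n_days) < cfg.missing_prob
            y = y.copy()
            y[miss] = np.nan
            series.append(LongitudinalSeries(pid, marker, days.copy(), y, batch_ids.copy()))
    return series, event_table


def generate_paired_samples(
    config: CohortConfig,
    effect_sizes: dict[str, float] | None = None,
) -> PairedSampleSet:
    """Paired stable/exacerbation concentrations for the discovery stage.

    Stable values are lognormal around each patient's baseline;
    exacerbation values are shifted by ``effect_sizes`` (log10 units,
    default 0) per marker.  With zero effect size the two members of a
    pair are exchangeable.  Output is on the linear scale.
    """
    cfg = config
    if cfg.n_patients < 2:
        raise ValueError("invalid CohortConfig.n_patients: need >= 2 for paired samples")
    effects = np.zeros(len(cfg.marker_names))
    if effect_sizes:
        unknown = set(effect_sizes) - set(cfg.marker_names)
        if unknown:
            raise ValueError(f"effect_sizes for unknown markers: {sorted(unknown)}")
        for i, mk in enumerate(cfg.marker_names):
            effects[i] = effect_sizes.get(mk, 0.0)
    if not np.all(np.isfinite(effects)):
        raise ValueError("effect sizes must be finite")

    # within-pair noise combines day-to-day fluctuation and assay noise
    pair_sd = float(np.hypot(cfg.ar_sd, cfg.obs_sd))
    rng = _rng(cfg.seed, _STREAM_PAIRED)
    n, m = cfg.n_patients, len(cfg.marker_names)
    baselines = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal((n, m))
    stable_log = baselines + pair_sd * rng.standard_normal((n, m))
    exac_log = baselines + effects[None, :] + pair_sd * rng.standard_normal((n, m))
    return PairedSampleSet(
        markers=cfg.marker_names,
        patient_ids=[f"P{p:03d}" for p in range(n)],
        stable=10.0 ** stable_log,
        exacerbation=10.0 ** exac_log,
    )
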