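"""Traffic-light decision rules and event-level alarm evaluation.

Daily risk scores (predicted days to exacerbation) are classified
green (score above the cut-off) or amber (at or below it); a day
turns red when at least 6 of the trailing 7 days (inclusive) are
amber or red.  Maximal runs of consecutive red days are merged into
single called events, and called events are scored against
clinician-diagnosed exacerbations using a 13-day pre-diagnosis
window: TP per true event with a red day inside its window, FN per
true event with none, FP per called event wholly outside all
windows, TN per stable day with a green outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DecisionConfig",
    "AlarmEvaluation",
    "GREEN",
    "AMBER",
    "RED",
    "classify_days",
    "call_events",
    "evaluate_alarms",
    "lead_time",
    "recovery_status",
]

logger = logging.getLogger(__name__)

GREEN, AMBER, RED = 0, 1, 2


@dataclass(frozen=True)
class DecisionConfig:
    """Operating points of the decision rules.

    ``amber_cutoff`` drives the daily green/amber decision (13.4 by
    default); ``roc_cutoff`` is the separate ROC operating point for
    windowed score classification (21.19) and plays no role in the
    traffic-light rule itself.
    """

    amber_cutoff: float = 13.4
    roc_cutoff: float = 21.19
    red_rule: tuple[int, int] = (6, 7)   # ambers required, trailing days
    window_days: int = 13
    recovery_check_day: int = 14

    def __post_init__(self) -> None:
        if self.red_rule[0] > self.red_rule[1]:
            raise ValueError("red_rule requires ambers <= trailing days")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")


@dataclass
class AlarmEvaluation:
    tp: int
    fn: int
    fp: int
    tn: int
    n_stable_days: int
    lead_times: list[int] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / self.n_stable_days if self.n_stable_days else float("nan")

    @property
    def ppv(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return 100.0 * self.tn / (self.fn + self.tn) if self.fn + self.tn else float("nan")


def classify_days(days, scores, config: DecisionConfig) -> np.ndarray:
    """Daily green/amber/red outcomes from risk scores.

    ``days`` must be increasing; gaps are filled by carrying the
    previous day's base colour forward (logged).  Green if score >
    amber_cutoff, amber otherwise; red on any day where >= 6 of the
    trailing 7 days (inclusive) are amber or red.
    """
    days = np.asarray(days, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    full_days = np.arange(days[0], days[-1] + 1)
    base = np.zeros(len(full_days), dtype=int)
    have = {int(d): s for d, s in zip(days, scores)}
    prev = AMBER if scores[0] <= config.amber_cutoff else GREEN
    for i, d in enumerate(full_days):
        if d in have:
            prev = AMBER if have[d] <= config.amber_cutoff else GREEN
        else:
            logger.info("day %d missing; carrying forward previous outcome", d)
        base[i] = prev

    need, trail = config.red_rule
    out = base.copy()
    contrib = np.zeros(len(full_days), dtype=int)
    for i in range(len(full_days)):
        contrib[i] = 1 if base[i] == AMBER else 0
        lo = max(i - trail + 1, 0)
        if contrib[lo:i + 1].sum() >= need:
            out[i] = RED
            contrib[i] = 1  # red days count as amber-or-red downstream
    return out


def call_events(outcomes) -> list[tuple[int, int]]:
    """Maximal runs of consecutive red days as (start, end) index pairs."""
    outcomes = np.asarray(outcomes, dtype=int)
    red = outcomes == RED
    events = []
    i = 0
    n = len(red)
    while i < n:
        if red[i]:
            j = i
            while j + 1 < n and red[j + 1]:
                j += 1
            events.append((i, j))
            i = j + 1
        else:
            i += 1
    return events


def _windows(true_events, window_days):
    wins = sorted((d - window_days, d) for d in true_events)
    for (a1, b1), (a2, _) in zip(wins, wins[1:]):
        if a2 <= b1:
            raise ValueError("overlapping true-event windows")
    return wins


def evaluate_alarms(outcomes, called, true_events, stable_days,
                    config: DecisionConfig) -> AlarmEvaluation:
    """Event-level confusion counts and predictive values.

    ``outcomes`` are daily colours indexed by day, ``called`` the
    merged red runs, ``true_events`` diagnosis days and
    ``stable_days`` the day indices counted for specificity/NPV.
    A run of consecutive reds counts as one called event, so
    tp + fn equals the number of true events and fp the number of
    called events wholly outside every window.
    """
    outcomes = np.asarray(outcomes, dtype=int)
    wins = _windows(true_events, config.window_days)
    tp = fn = 0
    red_days = np.flatnonzero(outcomes == RED)
    for lo, hi in wins:
        if np.any((red_days >= max(lo, 0)) & (red_days <= hi)):
            tp += 1
        else:
            fn += 1
    fp = 0
    for start, end in called:
        inside = any(start <= hi and end >= max(lo, 0) for lo, hi in wins)
        if not inside:
            fp += 1
    stable_days = np.asarray(stable_days, dtype=int)
    in_range = stable_days[(stable_days >= 0) & (stable_days < len(outcomes))]
    tn = int(np.sum(outcomes[in_range] == GREEN))
    leads = lead_time(called, true_events, outcomes, config)
    return AlarmEvaluation(tp=tp, fn=fn, fp=fp, tn=tn,
                           n_stable_days=len(in_range), lead_times=leads)


def lead_time(called, true_events, outcomes, config: DecisionConfig) -> list[int]:
    """Early-warning days per detected event.

    For each true event with a red day inside its window, the lead
    time is diagnosis day minus the first in-window red day of the
    earliest run intersecting the window; a run that began before the
    window is clamped to the window start, so leads never exceed the
    window length.
    """
    outcomes = np.asarray(outcomes, dtype=int)
    leads = []
    for d in sorted(true_events):
        lo, hi = max(d - config.window_days, 0), d
        for start, end in sorted(called):
            if start <= hi and end >= lo:
                leads.append(int(d - max(start, lo)))
                break
    return leads


def summarize_lead_times(leads) -> dict[str, float]:
    leads = np.asarray(leads, dtype=float)
    if len(leads) == 0:
        return {"median": float("nan"), "iqr_low": float("nan"),
                "iqr_high": float("nan"), "n": 0}
    q1, med, q3 = np.percentile(leads, [25, 50, 75])
    return {"median": float(med), "iqr_low": float(q1),
            "iqr_high": float(q3), "n": int(len(leads))}


def recovery_status(outcomes, true_events, config: DecisionConfig) -> float:
    """Fraction of events non-red at diagnosis + recovery_check_day.

    Events without sufficient follow-up are excluded (logged).
    Returns a percentage; NaN when no event has enough follow-up.
    """
    outcomes = np.asarray(outcomes, dtype=int)
    checked = nonred = 0
    for d in sorted(true_events):
        day = d + config.recovery_check_day
        if day >= len(outcomes):
            logger.info("event at day %d excluded: insufficient follow-up", d)
            continue
        checked += 1
        if outcomes[day] != RED:
            nonred += 1
    return 100.0 * nonred / checked if checked else float("nan")
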