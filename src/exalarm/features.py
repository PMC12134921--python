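"""Rolling-window temporal features with time-to-exacerbation labels.

A window spans 14 daily time points (anchor-13 ... anchor).  For each
marker and each window day the feature set holds the value, the
differential from the previous day, and the window-local integral
(cumulative sum from the window start), i.e. 14 x 3 = 42 values per
marker.  Each window is labelled with the time to the next
clinician-diagnosed exacerbation, with 200 denoting "no event within
the study horizon".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import EventTable
from .dlm import FilteredSeries

__all__ = [
    "WINDOW_DAYS",
    "WINDOW_POINTS",
    "TTE_HORIZON",
    "FeatureDatabase",
    "label_time_to_exacerbation",
    "extract_window",
    "feature_names",
    "build_database",
]

logger = logging.getLogger(__name__)

WINDOW_DAYS = 13          # lead-in span; the window covers 14 daily points
WINDOW_POINTS = WINDOW_DAYS + 1
TTE_HORIZON = 200         # standard time-to-exacerbation for non-exacerbators


def label_time_to_exacerbation(days, event_days, horizon: int = TTE_HORIZON) -> np.ndarray:
    """Days until the next event for each query day.

    tte(day) = next event day - day when a future (or same-day) event
    exists, else ``horizon``.
    """
    days = np.asarray(days, dtype=int)
    events = np.sort(np.asarray(list(event_days), dtype=int))
    tte = np.full(len(days), horizon, dtype=int)
    for i, d in enumerate(days):
        nxt = events[events >= d]
        if len(nxt):
            tte[i] = int(nxt[0] - d)
    return tte


def extract_window(values: np.ndarray, anchor_index: int) -> np.ndarray | None:
    """42-vector of (values, differentials, integrals) for one marker.

    ``values`` is a dense daily array; the window covers indices
    anchor-13 ... anchor.  The first differential uses the day before
    the window when available, else 0.  Returns None (and logs) when
    there is insufficient history or a non-finite value in the window.
    """
    values = np.asarray(values, dtype=float)
    start = anchor_index - WINDOW_DAYS
    if start < 0 or anchor_index >= len(values):
        logger.info("window at %d skipped: insufficient history", anchor_index)
        return None
    win = values[start:anchor_index + 1]
    if not np.all(np.isfinite(win)):
        logger.info("window at %d skipped: non-finite values", anchor_index)
        return None
    diffs = np.empty(WINDOW_POINTS)
    diffs[1:] = np.diff(win)
    if start >= 1 and np.isfinite(values[start - 1]):
        diffs[0] = win[0] - values[start - 1]
    else:
        diffs[0] = 0.0
    integrals = np.cumsum(win)
    return np.concatenate([win, diffs, integrals])


def feature_names(markers: list[str]) -> list[str]:
    """Column names matching the extract_window ordering per marker."""
    names = []
    for mk in markers:
        names += [f"{mk}|val{d}" for d in range(WINDOW_POINTS)]
        names += [f"{mk}|dif{d}" for d in range(WINDOW_POINTS)]
        names += [f"{mk}|int{d}" for d in range(WINDOW_POINTS)]
    return names


@dataclass
class FeatureDatabase:
    """Development and blinded production window sets.

    development: pre-exacerbation run-up windows plus a seeded random
    sample of stable-day windows.  production: windows anchored in
    post-event recovery spans plus all windows of patients with no
    events.  The two sets are disjoint by (patient, anchor_day).
    """

    markers: list[str]
    development: pd.DataFrame
    production: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def feature_columns(self) -> list[str]:
        order = self.manifest.get("feature_order")
        return list(order) if order else feature_names(self.markers)


def _dense_values(fs: FilteredSeries, n_days: int) -> np.ndarray:
    dense = np.full(n_days, np.nan)
    dense[fs.days] = fs.filtered_value
    return dense


def build_database(
    filtered: dict[tuple[str, str], FilteredSeries],
    events: EventTable,
    markers: list[str],
    n_days: int,
    recovery_days: int = 42,
    stable_ratio: float = 3.0,
    seed: int = 0,
) -> FeatureDatabase:
    """Assemble the labelled rolling-window feature database.

    Windows roll one day at a time.  Development anchors are the 14
    days up to each diagnosis plus a seeded random sample of stable
    anchors (>= 42 days from any event and outside recovery spans) at
    ``stable_ratio`` stable windows per exacerbation window.
    Production anchors are recovery-span days and every anchor of
    patients with no events.
    """
    patients = sorted({pid for pid, _ in filtered})
    cols = feature_names(markers)
    dev_rows, prod_rows = [], []
    rng = np.random.default_rng(seed)
    n_exac_windows = 0
    stable_pool: list[tuple[str, int, np.ndarray, int]] = []

    for pid in patients:
        dense = {}
        for mk in markers:
            key = (pid, mk)
            if key not in filtered:
                raise KeyError(f"missing filtered series for {key}")
            dense[mk] = _dense_values(filtered[key], n_days)
        ev = events.days_for(pid)
        all_days = np.arange(n_days)
        tte = label_time_to_exacerbation(all_days, ev)

        in_runup = np.zeros(n_days, dtype=bool)
        in_recovery = np.zeros(n_days, dtype=bool)
        near_event = np.zeros(n_days, dtype=bool)
        for d in ev:
            in_runup[max(d - WINDOW_DAYS, 0):d + 1] = True
            in_recovery[d + 1:min(d + recovery_days + 1, n_days)] = True
            near_event[max(d - recovery_days, 0):min(d + recovery_days + 1, n_days)] = True

        for anchor in range(WINDOW_DAYS, n_days):
            feats = []
            ok = True
            for mk in markers:
                v = extract_window(dense[mk], anchor)
                if v is None:
                    ok = False
                    break
                feats.append(v)
            if not ok:
                continue
            row = np.concatenate(feats)
            if not ev:
                prod_rows.append((pid, anchor, int(tte[anchor]), row))
            elif in_runup[anchor]:
                dev_rows.append((pid, anchor, int(tte[anchor]), row))
                n_exac_windows += 1
            elif in_recovery[anchor]:
                prod_rows.append((pid, anchor, int(tte[anchor]), row))
            elif not near_event[anchor]:
                stable_pool.append((pid, anchor, row, int(tte[anchor])))

    # seeded sample of stable-day windows for the development set
    n_stable = min(len(stable_pool), int(round(stable_ratio * n_exac_windows))) \
        if n_exac_windows else len(stable_pool)
    if stable_pool and n_stable:
        idx = rng.choice(len(stable_pool), size=n_stable, replace=False)
        for i in sorted(idx):
            pid, anchor, row, t = stable_pool[i]
            dev_rows.append((pid, anchor, t, row))

    if not dev_rows:
        raise ValueError("zero development windows; check events and history")

    def _frame(rows):
        if not rows:
            return pd.DataFrame(columns=["patient_id", "anchor_day", "tte"] + cols)
        meta = pd.DataFrame(
            [(p, a, t) for p, a, t, _ in rows],
            columns=["patient_id", "anchor_day", "tte"],
        )
        feats = pd.DataFrame([r for _, _, _, r in rows], columns=cols)
        return pd.concat([meta, feats], axis=1)

    dev = _frame(dev_rows).sort_values(["patient_id", "anchor_day"]).reset_index(drop=True)
    prod = _frame(prod_rows).sort_values(["patient_id", "anchor_day"]).reset_index(drop=True)
    manifest = {
        "markers": list(markers),
        "window_days": WINDOW_DAYS,
        "window_points": WINDOW_POINTS,
        "features_per_marker": 3 * WINDOW_POINTS,
        "recovery_days": recovery_days,
        "stable_ratio": stable_ratio,
        "seed": seed,
        "tte_horizon": TTE_HORIZON,
        "feature_order": cols,
    }
    return FeatureDatabase(list(markers), dev, prod, manifest)
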