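"""File formats and configuration.

Interchange is long-format CSV: cohort tables are
(patient_id, day, marker, value, batch_id[, missing_flag]) with
linear-scale concentrations and empty values for missing tests;
events tables are (patient_id, day).  Filtered series, feature
databases and model/evaluation reports use CSV/JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alarms import DecisionConfig
from .ann import ANNConfig
from .cohort import CohortConfig, EventTable, LongitudinalSeries
from .dlm import DLMPriors, FilteredSeries, MCMCConfig

__all__ = [
    "PipelineConfig",
    "read_longitudinal_csv",
    "write_longitudinal_csv",
    "read_events_csv",
    "write_events_csv",
    "write_filtered_csv",
    "read_filtered_csv",
    "load_config",
]

_COHORT_COLUMNS = ["patient_id", "day", "marker", "value", "batch_id"]


def write_longitudinal_csv(path, series_list: list[LongitudinalSeries]) -> None:
    """Write cohort series as long-format CSV (linear-scale values)."""
    rows = []
    for s in series_list:
        linear = np.where(np.isnan(s.values), np.nan, 10.0 ** s.values)
        for d, v, b in zip(s.days, linear, s.batch_ids):
            rows.append((s.patient_id, int(d), s.marker,
                         "" if np.isnan(v) else v, int(b),
                         int(np.isnan(v))))
    df = pd.DataFrame(rows, columns=_COHORT_COLUMNS + ["missing_flag"])
    df.to_csv(path, index=False)


def read_longitudinal_csv(path) -> list[LongitudinalSeries]:
    """Read a long-format cohort CSV into per-(patient, marker) series.

    Values are linear-scale concentrations (empty = missing) and are
    log10-transformed internally.  Validates the header, positivity
    of present values, and per-patient batch monotonicity.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "marker": str})
    extra = [c for c in df.columns if c not in _COHORT_COLUMNS + ["missing_flag"]]
    if extra or any(c not in df.columns for c in _COHORT_COLUMNS):
        raise ValueError(
            f"unexpected cohort CSV header {list(df.columns)}; "
            f"expected {_COHORT_COLUMNS} (+ optional missing_flag)")
    if not np.issubdtype(df["day"].dtype, np.integer):
        if not np.allclose(df["day"], df["day"].round()):
            raise ValueError("day column must be integer")
        df["day"] = df["day"].astype(int)
    bad = df.index[df["value"].notna() & (df["value"] <= 0)]
    if len(bad):
        raise ValueError(f"non-positive concentration at row {int(bad[0]) + 2}")
    out = []
    for (pid, marker), g in df.groupby(["patient_id", "marker"], sort=True):
        g = g.sort_values("day")
        diffs = np.diff(g["batch_id"].to_numpy())
        if np.any(diffs < 0):
            row = g.index[np.flatnonzero(diffs < 0)[0] + 1]
            raise ValueError(f"non-monotone batch_id at row {int(row) + 2}")
        values = np.where(g["value"].notna(), np.log10(g["value"]), np.nan)
        out.append(LongitudinalSeries(
            str(pid), str(marker), g["day"].to_numpy(int),
            values.astype(float), g["batch_id"].to_numpy(int)))
    return out


def write_events_csv(path, events: EventTable) -> None:
    rows = [(pid, d) for pid, days in sorted(events.events.items()) for d in sorted(days)]
    pd.DataFrame(rows, columns=["patient_id", "day"]).to_csv(path, index=False)


def read_events_csv(path) -> EventTable:
    df = pd.read_csv(path, dtype={"patient_id": str})
    table = EventTable()
    for pid, g in df.groupby("patient_id"):
        table.events[str(pid)] = sorted(int(d) for d in g["day"])
    return table


def write_filtered_csv(path, filtered: dict[tuple[str, str], FilteredSeries]) -> None:
    rows = []
    for (pid, mk), fs in sorted(filtered.items()):
        for d, v, sd in zip(fs.days, fs.filtered_value, fs.filtered_sd):
            rows.append((pid, int(d), mk, v, sd))
    pd.DataFrame(rows, columns=["patient_id", "day", "marker",
                                "filtered_value", "filtered_sd"]).to_csv(path, index=False)


def read_filtered_csv(path) -> dict[tuple[str, str], FilteredSeries]:
    df = pd.read_csv(path, dtype={"patient_id": str, "marker": str})
    out = {}
    for (pid, mk), g in df.groupby(["patient_id", "marker"], sort=True):
        g = g.sort_values("day")
        out[(str(pid), str(mk))] = FilteredSeries(
            str(pid), str(mk), g["day"].to_numpy(int),
            g["filtered_value"].to_numpy(float),
            g["filtered_sd"].to_numpy(float),
            np.ones(len(g), dtype=bool))
    return out


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; all randomness flows from ``seed``.

    Sub-seeds for each stage are derived from the root seed, and the
    default stage configurations are sized for a quick demonstration
    cohort (10 patients, 5 markers, 180 days).
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "discover", "fit_dlm", "features",
                               "train", "predict", "alarm", "evaluate")
    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(
        n_patients=10, n_days=180, exac_hazard=0.006, shift_magnitude=0.12))
    priors: DLMPriors = field(default_factory=DLMPriors)
    mcmc: MCMCConfig = field(default_factory=lambda: MCMCConfig(
        iterations=1200, burn_in=400, thin=2, store_states=False))
    ann: ANNConfig = field(default_factory=lambda: ANNConfig(
        max_steps=3, n_mc_splits=1, hidden_nodes_grid=(3, 5), epochs=150))
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    # "youden_dev": calibrate the amber cut-off on development windows;
    # "fixed": use decision.amber_cutoff as-is
    amber_mode: str = "youden_dev"
    discovery_effects: dict[str, float] = field(default_factory=lambda: {
        "NGAL": 0.12, "TIMP1": 0.10, "CRP": 0.10})
    stable_ratio: float = 3.0
    log_level: str = "INFO"


def _build(cls, mapping):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path) -> PipelineConfig:
    """Read a PipelineConfig from YAML; keys mirror the dataclass fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kw = dict(raw)
    for key, cls in (("cohort", CohortConfig), ("priors", DLMPriors),
                     ("mcmc", MCMCConfig), ("ann", ANNConfig),
                     ("decision", DecisionConfig)):
        if key in kw and isinstance(kw[key], dict):
            sub = dict(kw[key])
            for name in ("marker_names", "informative_markers",
                         "hidden_nodes_grid", "split_ratios", "red_rule", "stages"):
                if name in sub and isinstance(sub[name], list):
                    sub[name] = tuple(sub[name])
            kw[key] = _build(cls, sub)
    if "stages" in kw and isinstance(kw["stages"], list):
        kw["stages"] = tuple(kw["stages"])
    return _build(PipelineConfig, kw)


def dump_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
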