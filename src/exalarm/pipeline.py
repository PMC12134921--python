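"""End-to-end pipeline driver: simulate -> discover -> fit-dlm ->
features -> train -> predict -> alarm -> evaluate.

Each enabled stage writes its outputs under ``out_dir`` and feeds the
next stage; re-running with an identical configuration reproduces all
outputs (all randomness flows from the root seed).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import alarms, ann, discovery, dlm, features, metrics
from .cohort import generate_cohort, generate_paired_samples
from .io import (PipelineConfig, dump_json, write_events_csv,
                 write_filtered_csv, write_longitudinal_csv)

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"out_dir": str(out), "seed": config.seed}
    state: dict = {}
    for stage in config.stages:
        fn = _STAGES.get(stage)
        if fn is None:
            raise StageError(f"unknown stage: {stage}")
        logger.info("running stage %s", stage)
        try:
            fn(config, state, report, out)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
    dump_json(out / "report.json", report)
    return report


def _simulate(config, state, report, out):
    cohort_cfg = config.cohort.replace(seed=config.seed)
    series, events = generate_cohort(cohort_cfg)
    pairs = generate_paired_samples(cohort_cfg, config.discovery_effects)
    write_longitudinal_csv(out / "cohort.csv", series)
    write_events_csv(out / "events.csv", events)
    state.update(series=series, events=events, pairs=pairs, cohort_cfg=cohort_cfg)
    report["simulate"] = {
        "n_patients": cohort_cfg.n_patients,
        "n_days": cohort_cfg.n_days,
        "n_events": events.n_events,
        "n_missing": int(sum(s.missing.sum() for s in series)),
    }


def _discover(config, state, report, out):
    pairs = state["pairs"]
    screen = discovery.screen_biomarkers(pairs)
    pd.DataFrame([vars(r) for r in screen]).to_csv(out / "screen.csv", index=False)
    selected = [r.marker for r in screen if r.selected]
    candidates = selected if selected else list(pairs.markers)
    table = pd.DataFrame(
        np.vstack([np.log10(pairs.stable), np.log10(pairs.exacerbation)]),
        columns=list(pairs.markers))
    table["label"] = [0] * len(pairs.stable) + [1] * len(pairs.exacerbation)
    panel = discovery.fit_panel(table, candidates)
    scores = discovery.score_table(panel, table)
    roc = metrics.roc_auc(scores, table["label"], n_boot=500, seed=config.seed)
    youden = metrics.youden_cutoff(roc)
    conf = discovery.confusion_at_cutoff(scores, table["label"])
    ppv, npv = discovery.prevalence_adjusted_pv(conf.sensitivity,
                                               conf.specificity, 0.5)
    dump_json(out / "panel.json", {
        "intercept": panel.intercept,
        "coefficients": panel.coefficients,
        "retained_markers": panel.retained_markers,
    })
    report["discover"] = {
        "selected": selected,
        "retained": panel.retained_markers,
        "auc": roc.auc, "auc_ci": [roc.ci_low, roc.ci_high],
        "sensitivity": conf.sensitivity, "specificity": conf.specificity,
        "cutoff": conf.cutoff, "youden_cutoff": youden,
        "ppv_50": ppv, "npv_50": npv,
    }


def _fit_dlm(config, state, report, out):
    series = state["series"]
    mcmc = config.mcmc
    params_by = {}
    post_means = {}
    for i, s in enumerate(series):
        fit = dlm.fit_dlm(
            s, config.priors,
            dlm.MCMCConfig(mcmc.iterations, mcmc.burn_in, mcmc.thin,
                           seed=int(np.random.SeedSequence(
                               [config.seed, 17, i]).generate_state(1)[0] % (2**31)),
                           store_states=False))
        pm = fit.posterior_mean()
        params_by[(s.patient_id, s.marker)] = pm
        post_means[f"{s.patient_id}:{s.marker}"] = vars(pm)
    filtered = dlm.filter_cohort(series, params_by)
    write_filtered_csv(out / "filtered.csv", filtered)
    dump_json(out / "dlm_posterior_means.json", post_means)
    state["filtered"] = filtered
    report["fit_dlm"] = {"n_series": len(series),
                         "iterations": mcmc.iterations}


def _features(config, state, report, out):
    cohort_cfg = state["cohort_cfg"]
    filtered = state.get("filtered")
    if filtered is None:
        # documented fallback: features on raw log10 values
        filtered = {
            (s.patient_id, s.marker): dlm.FilteredSeries(
                s.patient_id, s.marker, s.days, s.values,
                np.zeros(len(s.days)), ~s.missing)
            for s in state["series"]
        }
        report.setdefault("features", {})["fallback_raw_values"] = True
    db = features.build_database(
        filtered, state["events"], list(cohort_cfg.marker_names),
        cohort_cfg.n_days, recovery_days=cohort_cfg.recovery_days,
        stable_ratio=config.stable_ratio, seed=config.seed)
    db.development.to_csv(out / "features_development.csv", index=False)
    db.production.to_csv(out / "features_production.csv", index=False)
    dump_json(out / "features_manifest.json", db.manifest)
    state["db"] = db
    rep = report.setdefault("features", {})
    rep.update(n_development=len(db.development), n_production=len(db.production))


def _train(config, state, report, out):
    db = state["db"]
    cfg = ann.ANNConfig(
        max_steps=config.ann.max_steps,
        split_ratios=config.ann.split_ratios,
        n_mc_splits=config.ann.n_mc_splits,
        hidden_nodes_grid=config.ann.hidden_nodes_grid,
        selection_hidden=config.ann.selection_hidden,
        epochs=config.ann.epochs,
        learning_rate=config.ann.learning_rate,
        momentum=config.ann.momentum,
        patience=config.ann.patience,
        seed=config.seed,
    )
    trace = ann.stepwise_select(db, cfg)
    model = ann.train_final(db, trace.selected_inputs, cfg)
    (out / "model.json").write_text(model.to_json())
    state["model"] = model
    report["train"] = {
        "selected_inputs": trace.selected_inputs,
        "panel": trace.panel,
        "hidden": model.hidden,
        "step_errors": [s.chosen_error for s in trace.steps],
    }


def _predict(config, state, report, out):
    db, model = state["db"], state["model"]
    frames = []
    for name, frame in (("development", db.development),
                        ("production", db.production)):
        if frame.empty:
            continue
        risk = ann.predict_risk(model, frame)
        frames.append(pd.DataFrame({
            "patient_id": frame["patient_id"],
            "day": frame["anchor_day"],
            "tte": frame["tte"],
            "risk_score": risk,
            "subset": name,
        }))
    risk_df = pd.concat(frames, ignore_index=True)
    risk_df.to_csv(out / "risk.csv", index=False)
    state["risk"] = risk_df
    report["predict"] = {"n_scored_days": len(risk_df)}


def _alarm(config, state, report, out):
    risk_df, events = state["risk"], state["events"]
    cohort_cfg = state["cohort_cfg"]
    dcfg = config.decision
    if getattr(config, "amber_mode", "fixed") == "youden_dev":
        # the amber operating point belongs to the score scale of the
        # trained network; re-derive it on development windows only
        dev = risk_df[risk_df["subset"] == "development"]
        labels = (dev["tte"] <= dcfg.window_days).astype(int).to_numpy()
        if labels.min() != labels.max():
            roc = metrics.roc_auc(-dev["risk_score"].to_numpy(), labels,
                                  n_boot=0)
            import dataclasses as _dc
            dcfg = _dc.replace(dcfg,
                               amber_cutoff=-metrics.youden_cutoff(roc))
    tp = fn = fp = tn = 0
    n_stable = 0
    leads: list[int] = []
    daily_rows = []
    for pid, g in risk_df.groupby("patient_id"):
        g = g.sort_values("day").drop_duplicates("day")
        outcomes = alarms.classify_days(g["day"].to_numpy(),
                                        g["risk_score"].to_numpy(), dcfg)
        day0 = int(g["day"].min())
        full = np.full(day0 + len(outcomes), alarms.GREEN)
        full[day0:] = outcomes
        ev = events.days_for(pid)
        called = [(s + day0, e + day0) for s, e in alarms.call_events(outcomes)]
        windows = set()
        for d in ev:
            windows.update(range(d - dcfg.window_days, d + 1))
            windows.update(range(d + 1, d + cohort_cfg.recovery_days + 1))
        stable_days = [d for d in range(day0, day0 + len(outcomes))
                       if d not in windows]
        res = alarms.evaluate_alarms(full, called, ev, stable_days, dcfg)
        tp += res.tp; fn += res.fn; fp += res.fp; tn += res.tn
        n_stable += res.n_stable_days
        leads += res.lead_times
        for i, o in enumerate(outcomes):
            daily_rows.append((pid, day0 + i, int(o)))
    pd.DataFrame(daily_rows, columns=["patient_id", "day", "outcome"]).to_csv(
        out / "daily_outcomes.csv", index=False)
    total = alarms.AlarmEvaluation(tp, fn, fp, tn, n_stable, leads)
    report["alarm"] = {
        "amber_cutoff": dcfg.amber_cutoff,
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "n_stable_days": n_stable,
        "sensitivity": total.sensitivity, "specificity": total.specificity,
        "ppv": total.ppv, "npv": total.npv,
        "lead_times": alarms.summarize_lead_times(leads),
    }
    dump_json(out / "alarm_evaluation.json", report["alarm"])


def _evaluate(config, state, report, out):
    risk_df = state["risk"]
    labels = (risk_df["tte"] <= config.decision.window_days).astype(int).to_numpy()
    if labels.min() == labels.max():
        report["evaluate"] = {"windowed_auc": None,
                              "note": "single class; no windowed ROC"}
        return
    # lower predicted time-to-exacerbation = higher risk
    roc = metrics.roc_auc(-risk_df["risk_score"].to_numpy(), labels,
                          n_boot=500, seed=config.seed)
    report["evaluate"] = {
        "windowed_auc": roc.auc,
        "auc_ci": [roc.ci_low, roc.ci_high],
        "n_window_days": int(labels.sum()),
        "n_days": int(len(labels)),
    }
    dump_json(out / "evaluation.json", report["evaluate"])


_STAGES = {
    "simulate": _simulate,
    "discover": _discover,
    "fit_dlm": _fit_dlm,
    "features": _features,
    "train": _train,
    "predict": _predict,
    "alarm": _alarm,
    "evaluate": _evaluate,
}
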