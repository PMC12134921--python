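"""Paired biomarker discovery and the logistic panel model.

Implements the discovery/validation stage: per-marker paired
screening (paired t-test + ROC AUC with the AUC >= 0.59 or <= 0.41
and p < 0.05 selection rule), backward stepwise logistic regression
on log10 concentrations, the panel probability score, and
prevalence-adjusted predictive values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import PairedSampleSet
from .metrics import paired_t_test, roc_auc

__all__ = [
    "ScreenResult",
    "PanelModel",
    "ConfusionSummary",
    "SeparationError",
    "screen_biomarkers",
    "fit_panel",
    "score",
    "prevalence_adjusted_pv",
    "confusion_at_cutoff",
]

AUC_UPPER = 0.59
AUC_LOWER = 0.41
P_THRESHOLD = 0.05
DEFAULT_CUTOFF = 0.39


class SeparationError(RuntimeError):
    """Raised when the logistic fit is perfectly separated."""


@dataclass
class ScreenResult:
    marker: str
    auc: float
    p_value: float
    selected: bool


@dataclass
class PanelModel:
    """Logistic panel: P(exacerbation) = logit^-1(b0 + sum b_i * x_i)."""

    intercept: float
    coefficients: dict[str, float]
    retained_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.retained_markers:
            self.retained_markers = list(self.coefficients)
        for mk in self.retained_markers:
            if not np.isfinite(self.coefficients[mk]):
                raise ValueError(f"non-finite coefficient for marker {mk}")


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int
    cutoff: float

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)


def select_rule(auc: float, p_value: float) -> bool:
    """Predefined screening rule: AUC >= 0.59 or <= 0.41, and p < 0.05."""
    return (auc >= AUC_UPPER or auc <= AUC_LOWER) and p_value < P_THRESHOLD


def screen_biomarkers(pairs: PairedSampleSet,
                      p_adjust: str | None = None) -> list[ScreenResult]:
    """Screen each marker by paired t-test and ROC AUC on log10 values.

    AUC compares exacerbation against stable concentrations; markers
    with all-missing values are skipped with a warning, and
    zero-variance differences report p = 1.  Screening is unadjusted
    for multiplicity by default; ``p_adjust`` accepts any method name
    understood by statsmodels' ``multipletests`` (e.g. "bonferroni",
    "holm") to adjust the p-values before the selection rule.
    """
    results: list[ScreenResult] = []
    log_stable = np.log10(pairs.stable)
    log_exac = np.log10(pairs.exacerbation)
    for j, marker in enumerate(pairs.markers):
        xs, xe = log_stable[:, j], log_exac[:, j]
        ok = np.isfinite(xs) & np.isfinite(xe)
        if ok.sum() < 2:
            warnings.warn(f"marker {marker}: fewer than 2 complete pairs; skipped",
                          stacklevel=2)
            continue
        xs, xe = xs[ok], xe[ok]
        _, p = paired_t_test(xs, xe)
        scores = np.concatenate([xs, xe])
        labels = np.concatenate([np.zeros(len(xs), int), np.ones(len(xe), int)])
        auc = roc_auc(scores, labels, n_boot=0).auc
        results.append(ScreenResult(marker, auc, p, select_rule(auc, p)))
    if p_adjust is not None and results:
        from statsmodels.stats.multitest import multipletests
        _, adj, _, _ = multipletests([r.p_value for r in results],
                                     method=p_adjust)
        for r, q in zip(results, adj):
            r.p_value = float(q)
            r.selected = select_rule(r.auc, r.p_value)
    return results


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise SeparationError("perfect separation: unstable coefficients")
    if np.any(np.abs(res.params) > 50):
        raise SeparationError("perfect separation: diverging coefficients")
    return res


def fit_panel(data: pd.DataFrame, candidates: list[str],
              label_col: str = "label", alpha: float = P_THRESHOLD) -> PanelModel:
    """Backward stepwise logistic regression on log10 concentrations.

    Starts from all ``candidates`` and repeatedly drops the covariate
    with the largest Wald p-value above ``alpha`` until all retained
    covariates are significant or a single covariate remains.  Ties
    between equally insignificant covariates drop the
    lexicographically later marker name, making the path
    deterministic and order-independent.
    """
    if not candidates:
        raise ValueError("need at least one candidate marker")
    y = np.asarray(data[label_col], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    retained = sorted(candidates)
    while True:
        res = _fit_logit(y, data[retained])
        pvals = {mk: float(res.pvalues[mk]) for mk in retained}
        worst_p = max(pvals.values())
        if worst_p <= alpha or len(retained) == 1:
            coefs = {mk: float(res.params[mk]) for mk in retained}
            return PanelModel(float(res.params["const"]), coefs, list(retained))
        # drop the worst; ties -> lexicographically later name
        worst = max(mk for mk, p in pvals.items() if p == worst_p)
        retained.remove(worst)


def score(model: PanelModel, sample: dict[str, float]) -> float:
    """Panel probability score: inverse logit of the linear predictor."""
    eta = model.intercept
    for mk in model.retained_markers:
        if mk not in sample or not np.isfinite(sample[mk]):
            raise ValueError(f"missing value for retained marker {mk}")
        eta += model.coefficients[mk] * sample[mk]
    return float(1.0 / (1.0 + np.exp(-eta)))


def score_table(model: PanelModel, data: pd.DataFrame) -> np.ndarray:
    """Vectorised probability scores for a wide table of log10 values."""
    eta = np.full(len(data), model.intercept)
    for mk in model.retained_markers:
        eta += model.coefficients[mk] * np.asarray(data[mk], dtype=float)
    return 1.0 / (1.0 + np.exp(-eta))


def confusion_at_cutoff(scores, labels, cutoff: float = DEFAULT_CUTOFF) -> ConfusionSummary:
    """Confusion counts calling exacerbation when score >= cutoff."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    call = scores >= cutoff
    tp = int(np.sum(call & (labels == 1)))
    fp = int(np.sum(call & (labels == 0)))
    fn = int(np.sum(~call & (labels == 1)))
    tn = int(np.sum(~call & (labels == 0)))
    return ConfusionSummary(tp, fp, fn, tn, cutoff)


def prevalence_adjusted_pv(sensitivity: float, specificity: float,
                           prevalence: float) -> tuple[float, float]:
    """Prevalence-adjusted PPV and NPV, in percent.

    ``sensitivity`` and ``specificity`` are percentages, ``prevalence``
    a proportion.  PPV = 100*se*pi / (se*pi + (1-sp)(1-pi)) and
    NPV = 100*sp*(1-pi) / (sp*(1-pi) + (1-se)*pi) with se, sp as
    proportions.
    """
    if not (0 <= sensitivity <= 100 and 0 <= specificity <= 100 and 0 <= prevalence <= 1):
        raise ValueError("sensitivity/specificity in [0,100], prevalence in [0,1]")
    se, sp, pi = sensitivity / 100.0, specificity / 100.0, prevalence
    ppv_den = se * pi + (1 - sp) * (1 - pi)
    npv_den = sp * (1 - pi) + (1 - se) * pi
    if ppv_den == 0 or npv_den == 0:
        raise ZeroDivisionError("predictive value undefined: zero denominator")
    return 100.0 * se * pi / ppv_den, 100.0 * sp * (1 - pi) / npv_den
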