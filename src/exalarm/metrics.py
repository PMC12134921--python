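"""Shared statistics: ROC/AUC with bootstrap CIs, Youden cut-offs,
paired t-tests and compliance arithmetic."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "roc_auc",
    "youden_cutoff",
    "paired_t_test",
    "compliance_summary",
]


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    cutoffs: np.ndarray        # candidate thresholds, ascending
    sensitivity: np.ndarray    # P(score >= cutoff | positive), per cutoff
    specificity: np.ndarray    # P(score <  cutoff | negative), per cutoff


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC analysis of ``scores`` against binary ``labels``.

    AUC uses the rank (Mann-Whitney) formulation with ties counted
    1/2; the 95% CI is a seeded stratified bootstrap (``n_boot``
    resamples within each class; set ``n_boot=0`` to skip).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")

    auc = _rank_auc(scores, labels)

    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cutoffs = np.unique(scores)
    # call positive when score >= cutoff
    sens = np.array([(pos >= c).mean() for c in cutoffs])
    spec = np.array([(neg < c).mean() for c in cutoffs])

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            ps = rng.choice(pos, size=n_pos, replace=True)
            ns = rng.choice(neg, size=n_neg, replace=True)
            bs = np.concatenate([ps, ns])
            bl = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
            boots[b] = _rank_auc(bs, bl)
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        ci_low, ci_high = min(ci_low, auc), max(ci_high, auc)
    else:
        ci_low = ci_high = auc
    return RocResult(auc, float(ci_low), float(ci_high), n_pos, n_neg,
                     cutoffs, sens, spec)


def youden_cutoff(roc: RocResult) -> float:
    """Cut-off maximising Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the lower cut-off.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j == j.max())[0]
    return float(roc.cutoffs[best])


def paired_t_test(x_stable, x_exac) -> tuple[float, float]:
    """Two-sided paired t-test on the differences exac - stable.

    Zero-variance differences give (0.0, 1.0) with a warning.
    """
    x_stable = np.asarray(x_stable, dtype=float)
    x_exac = np.asarray(x_exac, dtype=float)
    if x_stable.shape != x_exac.shape or x_stable.size < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    d = x_exac - x_stable
    sd = d.std(ddof=1)
    if sd == 0.0:
        warnings.warn("zero-variance paired differences; p reported as 1",
                      stacklevel=2)
        return 0.0, 1.0
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def compliance_summary(
    n_expected: int,
    n_done: int,
    n_valid: int,
    decimals_done: int = 1,
    decimals_valid: int = 0,
) -> tuple[float, float]:
    """(% of expected tests done, % of done tests valid).

    Rounding defaults follow the usual reporting convention of one
    decimal for the completion rate and whole percent for validity.
    """
    if not (0 <= n_valid <= n_done <= n_expected):
        raise ValueError(
            f"counts must satisfy 0 <= n_valid ({n_valid}) <= n_done "
            f"({n_done}) <= n_expected ({n_expected})"
        )
    if n_expected == 0:
        raise ValueError("n_expected must be positive")
    pct_done = round(100.0 * n_done / n_expected, decimals_done)
    if n_done == 0:
        warnings.warn("no tests done; valid-of-done reported as 0", stacklevel=2)
        pct_valid = 0.0
    else:
        pct_valid = round(100.0 * n_valid / n_done, decimals_valid)
    return float(pct_done), float(pct_valid)
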