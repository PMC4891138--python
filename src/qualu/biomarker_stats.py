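"""Group comparisons and ROC-based cutoff selection for PUMA as a biomarker.

Tumors are the positive, higher-PUMA class throughout.  The AUC is computed
from the Mann-Whitney rank statistic (mid-ranks for ties); the optimal cutoff
maximizes Youden's J = sensitivity + specificity - 1, ties broken toward
higher specificity, and is reported as the midpoint between the two observed
values bracketing the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics


@dataclass(frozen=True)
class RocResult:
    auc: float
    best_cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int


def auc_rank(normal_values: Sequence[float], tumor_values: Sequence[float]) -> float:
    """AUC via the rank (Mann-Whitney U) statistic with mid-ranks for ties."""
    neg = np.asarray(normal_values, dtype=float)
    pos = np.asarray(tumor_values, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([neg, pos]))
    u = ranks[neg.size :].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (neg.size * pos.size))


def auc_trapezoid(
    normal_values: Sequence[float], tumor_values: Sequence[float]
) -> float:
    """Trapezoidal area under the empirical ROC curve (cross-check route)."""
    neg = np.asarray(normal_values, dtype=float)
    pos = np.asarray(tumor_values, dtype=float)
    y = np.concatenate([np.zeros(neg.size), np.ones(pos.size)])
    fpr, tpr, _ = metrics.roc_curve(y, np.concatenate([neg, pos]))
    return float(metrics.auc(fpr, tpr))


def roc_analysis(
    normal_values: Sequence[float], tumor_values: Sequence[float]
) -> RocResult:
    """ROC of tumor (positive, high) vs normal (negative, low) PUMA."""
    neg = np.asarray(normal_values, dtype=float)
    pos = np.asarray(tumor_values, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both groups must be non-empty")
    values = np.unique(np.concatenate([neg, pos]))
    # candidate thresholds: midpoints between consecutive observed values,
    # plus one below and one above the observed range
    mids = (values[:-1] + values[1:]) / 2.0 if values.size > 1 else np.array([])
    candidates = np.concatenate([[values[0] - 1.0], mids, [values[-1] + 1.0]])
    best = None
    for t in candidates:
        sens = float((pos > t).mean())
        spec = float((neg <= t).mean())
        j = sens + spec - 1.0
        # ties in J broken toward higher specificity (i.e. higher threshold)
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and spec > best[2]
        ):
            best = (j, sens, spec, float(t))
    _, sens, spec, cutoff = best
    return RocResult(
        auc=auc_rank(neg, pos),
        best_cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def roc_curve_points(
    normal_values: Sequence[float], tumor_values: Sequence[float]
) -> "np.ndarray":
    """(threshold, fpr, tpr) rows of the empirical ROC curve, for plotting."""
    neg = np.asarray(normal_values, dtype=float)
    pos = np.asarray(tumor_values, dtype=float)
    y = np.concatenate([np.zeros(neg.size), np.ones(pos.size)])
    fpr, tpr, thr = metrics.roc_curve(y, np.concatenate([neg, pos]))
    return np.column_stack([thr, fpr, tpr])


def group_compare(groups: Sequence[Sequence[float]], paired: bool = False) -> float:
    """Nonparametric group comparison p-value.

    Two groups: Mann-Whitney U (exact when both n <= 8 and there are no ties,
    normal approximation with tie correction otherwise); paired two-group:
    Wilcoxon signed-rank.  More than two groups: Kruskal-Wallis.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 3 for g in groups):
        raise ValueError("each group needs >= 3 values")
    if paired:
        if len(groups) != 2:
            raise ValueError("paired comparison requires exactly 2 groups")
        a, b = groups
        if a.size != b.size:
            raise ValueError("paired groups must have equal lengths")
        return float(stats.wilcoxon(a, b).pvalue)
    if len(groups) == 2:
        a, b = groups
        pooled = np.concatenate([a, b])
        exact = a.size <= 8 and b.size <= 8 and np.unique(pooled).size == pooled.size
        method = "exact" if exact else "asymptotic"
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    return float(stats.kruskal(*groups).pvalue)
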