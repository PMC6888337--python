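"""Per-gene biomarker evaluation: ROC/AUC with DeLong confidence interval,
two-group and multi-group expression tests.

AUC is the Mann-Whitney probability P(score_pos > score_neg) with the
mid-rank tie convention; the confidence interval uses DeLong's structural
components.  Down-regulated markers are reported with a direction flag and
a direction-corrected AUC >= 0.5 (the convention the source analyses use
for discriminative down-regulated genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InvalidLabelsError
from .expression import ExpressionMatrix

__all__ = ["RocResult", "roc_auc", "two_group_test", "multi_group_tests",
           "marker_report"]


@dataclass
class RocResult:
    """AUC, DeLong CI and the ROC curve itself."""

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    direction: str                  # 'up' (raw AUC >= 0.5) or 'down' (flipped)
    curve: pd.DataFrame = field(repr=False, default=None)  # columns fpr, tpr


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """Variance of the AUC from DeLong's placement values."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    rk_all = _midranks(allv)
    rk_pos = _midranks(pos)
    rk_neg = _midranks(neg)
    v10 = (rk_all[:m] - rk_pos) / n            # per positive
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m      # per negative
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels, alpha: float = 0.05) -> RocResult:
    """ROC analysis of ``scores`` against binary ``labels`` (1 = positive).

    AUC = (concordant + 0.5 * ties) / (n_pos * n_neg) via mid-ranks; if the
    raw AUC falls below 0.5 the direction-corrected value 1 - AUC is
    reported with ``direction='down'``.  CI is the DeLong normal interval,
    clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise InvalidLabelsError("both classes must be present for ROC")
    direction = "up"
    rk = _midranks(scores)
    u = rk[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2.0
    auc = u / (len(pos) * len(neg))
    work = scores
    if auc < 0.5:
        direction = "down"
        auc = 1.0 - auc
        work = -scores
        pos, neg = -pos, -neg
    var = _delong_variance(pos, neg, auc)
    zq = stats.norm.ppf(1 - alpha / 2)
    half = zq * np.sqrt(max(var, 0.0))
    ci_low = float(np.clip(auc - half, 0.0, min(auc, 1.0)))
    ci_high = float(np.clip(auc + half, max(auc, 0.0), 1.0))

    # explicit curve on the direction-corrected scores
    thresh = np.unique(work)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresh:
        tpr.append(np.count_nonzero(pos >= t) / len(pos))
        fpr.append(np.count_nonzero(neg >= t) / len(neg))
    if tpr[-1] != 1.0 or fpr[-1] != 1.0:
        tpr.append(1.0)
        fpr.append(1.0)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return RocResult(auc=float(auc), ci_low=ci_low, ci_high=ci_high,
                     n_pos=int((labels == 1).sum()), n_neg=int((labels == 0).sum()),
                     direction=direction, curve=curve)


def two_group_test(values_a, values_b, equal_var: bool = False) -> float:
    """Two-tailed t-test p-value (Welch by default; ``equal_var=True`` for
    the pooled-variance Student form)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidLabelsError("both groups need >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def multi_group_tests(values, groups) -> dict:
    """Kruskal-Wallis, one-way ANOVA and Tukey HSD pairwise p-values.

    ``groups`` is a label per value; >= 3 groups each with >= 2 values.
    Returns ``{'kruskal_wallis_p', 'anova_p', 'tukey'}`` where ``tukey`` is
    a DataFrame (group1, group2, p_adj).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = list(pd.unique(labels))
    if len(uniq) < 3:
        raise InvalidLabelsError("multi-group tests need >= 3 groups (Tukey)")
    parts = [values[labels == g] for g in uniq]
    if any(len(p) < 2 for p in parts):
        raise InvalidLabelsError("each group needs >= 2 values")
    kw = stats.kruskal(*parts)
    an = stats.f_oneway(*parts)
    tk = pairwise_tukeyhsd(values, labels)
    rows = tk.summary().data[1:]
    tukey = pd.DataFrame({
        "group1": [row[0] for row in rows],
        "group2": [row[1] for row in rows],
        "p_adj": np.asarray(tk.pvalues, dtype=float),
    })
    return {"kruskal_wallis_p": float(kw.pvalue), "anova_p": float(an.pvalue),
            "tukey": tukey}


def marker_report(matrix: ExpressionMatrix, genes, positive_group,
                  negative_group) -> pd.DataFrame:
    """ROC + Welch t per gene for positive vs negative group; TSV-ready."""
    pos = matrix.samples_in_group(positive_group)
    neg = matrix.samples_in_group(negative_group)
    rows = []
    for g in genes:
        if g not in matrix.values.index:
            continue
        row = matrix.values.loc[g]
        scores = np.concatenate([row[pos].to_numpy(), row[neg].to_numpy()])
        labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
        roc = roc_auc(scores, labels)
        tp = two_group_test(row[pos], row[neg])
        rows.append({"gene": g, "auc": roc.auc, "ci_low": roc.ci_low,
                     "ci_high": roc.ci_high, "direction": roc.direction,
                     "t_p": tp})
    return pd.DataFrame(rows, columns=["gene", "auc", "ci_low", "ci_high",
                                       "direction", "t_p"])
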