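"""Significance Analysis of Microarrays, two-class unpaired, from scratch.

The moderated statistic is d_i = r_i / (s_i + s0) with

    r_i = xbar_i(2) - xbar_i(1)
    s_i = sqrt( [(1/n1 + 1/n2) / (n1 + n2 - 2)] * [SS_1(i) + SS_2(i)] )

where SS_g is the within-group sum of squared deviations.  The fudge factor
s0 is chosen from percentiles of {s_i} to make the spread of d independent
of s (coefficient-of-variation criterion).  The null distribution comes
from label permutations: the expected order statistics dbar_(i) are the
mean of the sorted permuted d; a threshold Delta calls the genes beyond the
first sorted positions where |d_(i) - dbar_(i)| >= Delta, and

    FDR(Delta) = pi0 * median over permutations of false calls / #called

with pi0 estimated by the interquartile method.  The reported delta is the
smallest grid value with FDR <= target; a gene's q-value is the smallest
FDR at which it is called.

Model/Results interface::

    res = SAM(matrix, group_order=("HO", "NASH")).fit(SamParams(seed=1))
    res.summary()          # text table
    res.table              # per-gene DataFrame (r, s, d, fold_change, q, called)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidLabelsError, InvalidParameterError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["SamParams", "SAM", "SAMResults", "sam_d_statistics", "estimate_s0",
           "sam_two_class"]


@dataclass
class SamParams:
    """Tuning knobs of the SAM run.

    n_permutations : label permutations for the null (>= 50); if it reaches
        the number of distinct label arrangements, all arrangements are
        enumerated exactly instead.
    s0_percentiles : candidate fudge-factor grid, percentiles of {s_i}.
    fdr_target : permutation FDR at which genes are called.
    n_delta : size of the evenly spaced Delta grid.
    """

    n_permutations: int = 500
    s0_percentiles: tuple = tuple(range(0, 101, 5))
    fdr_target: float = 0.05
    n_delta: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 50:
            raise InvalidParameterError("n_permutations must be >= 50")
        if not 0.0 < self.fdr_target < 1.0:
            raise InvalidParameterError("fdr_target must be in (0, 1)")
        if len(self.s0_percentiles) < 1:
            raise InvalidParameterError("need at least one s0 candidate")


def _two_group_index(matrix: ExpressionMatrix, group_order=None):
    labels = matrix.group_labels()
    if group_order is None:
        group_order = tuple(sorted(labels))
    if len(labels) != 2 or set(group_order) != set(labels):
        raise InvalidLabelsError(
            f"exactly two groups required, got {labels!r} vs order {group_order!r}")
    samples = list(matrix.values.columns)
    idx1 = np.array([i for i, s in enumerate(samples)
                     if matrix.groups[s] == group_order[0]])
    idx2 = np.array([i for i, s in enumerate(samples)
                     if matrix.groups[s] == group_order[1]])
    if len(idx1) < 2 or len(idx2) < 2:
        raise InvalidLabelsError("each group needs >= 2 samples")
    return group_order, idx1, idx2


def _rs_from_split(x: np.ndarray, idx1: np.ndarray, idx2: np.ndarray):
    """Vectorized r_i and s_i for one assignment of columns to groups."""
    n1, n2 = len(idx1), len(idx2)
    x1, x2 = x[:, idx1], x[:, idx2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2) * ss)
    return m2 - m1, s


def sam_d_statistics(matrix: ExpressionMatrix, group_order=None, s0: float = 0.0):
    """Per-gene (r, s, d) for the two-class unpaired SAM statistic."""
    _, idx1, idx2 = _two_group_index(matrix, group_order)
    x = matrix.values.to_numpy(dtype=float)
    r, s = _rs_from_split(x, idx1, idx2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(s + s0 > 0, r / (s + s0), 0.0)
    return r, s, d


def estimate_s0(r: np.ndarray, s: np.ndarray,
                percentiles=tuple(range(0, 101, 5))) -> float:
    """Fudge factor minimizing the coefficient of variation of the spread of
    d across the scale of s.

    For each candidate s0 (a percentile of {s_i}), genes are cut into up to
    100 quantile bins of s_i; the MAD of d = r/(s+s0) is taken per bin and
    the candidate minimizing the CV of those MADs wins (ties: smaller s0).
    """
    r = np.asarray(r, float)
    s = np.asarray(s, float)
    m = len(s)
    if m == 0 or np.all(s == 0):
        raise DegenerateDataError("all per-gene scales s_i are zero")
    if m < 100:
        warnings.warn(f"estimate_s0 on only {m} genes; s0 is unstable below 100",
                      stacklevel=2)
    cands = np.percentile(s, sorted(percentiles))
    if len(cands) == 1:
        return float(cands[0])
    n_bins = min(100, max(2, m // 5))
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    best_cv, best_s0 = np.inf, float(cands[0])
    for s0 in cands:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(s + s0 > 0, r / (s + s0), 0.0)
        mads = []
        for b in range(n_bins):
            db = d[bins == b]
            if db.size:
                mads.append(np.median(np.abs(db - np.median(db))))
        mads = np.array(mads)
        mu = mads.mean()
        if mu == 0:
            continue
        cv = mads.std(ddof=0) / mu
        if cv < best_cv - 1e-12 or (abs(cv - best_cv) <= 1e-12 and s0 < best_s0):
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _permutation_splits(n: int, n1: int, params: SamParams):
    """Column index splits for the null; exact enumeration when feasible."""
    total = comb(n, n1)
    if params.n_permutations >= total:
        warnings.warn(
            f"n_permutations={params.n_permutations} >= {total} distinct "
            "label arrangements; enumerating exactly", stacklevel=3)
        cols = np.arange(n)
        splits = []
        for c in combinations(range(n), n1):
            i1 = np.array(c)
            i2 = np.setdiff1d(cols, i1)
            splits.append((i1, i2))
        return splits, True
    rng = np.random.default_rng(params.seed)
    splits = []
    for _ in range(params.n_permutations):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[:n1]), np.sort(perm[n1:])))
    return splits, False


class SAM:
    """Two-class unpaired SAM model over an :class:`ExpressionMatrix`.

    ``group_order=(reference, test)``: d > 0 means higher in the test group.
    """

    def __init__(self, matrix: ExpressionMatrix, group_order=None):
        self.matrix = matrix
        self.group_order, self._idx1, self._idx2 = _two_group_index(matrix, group_order)

    def fit(self, params: SamParams | None = None) -> "SAMResults":
        params = params or SamParams()
        x = self.matrix.values.to_numpy(dtype=float)
        genes = np.array(self.matrix.values.index)
        m = len(genes)
        r, s = _rs_from_split(x, self._idx1, self._idx2)
        s0 = estimate_s0(r, s, params.s0_percentiles) if m > 1 else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(s + s0 > 0, r / (s + s0), 0.0)

        order = np.argsort(d, kind="stable")
        d_sorted = d[order]

        splits, exact = _permutation_splits(x.shape[1], len(self._idx1), params)
        B = len(splits)
        perm_sorted = np.empty((B, m))
        for b, (i1, i2) in enumerate(splits):
            rb, sb = _rs_from_split(x, i1, i2)
            with np.errstate(divide="ignore", invalid="ignore"):
                db = np.where(sb + s0 > 0, rb / (sb + s0), 0.0)
            perm_sorted[b] = np.sort(db)
        dbar = perm_sorted.mean(axis=0)

        q25, q75 = np.percentile(perm_sorted, [25, 75])
        pi0 = min(1.0, np.count_nonzero((d >= q25) & (d <= q75)) / (0.5 * m))

        diff = d_sorted - dbar
        dmax = np.abs(diff).max() if m else 0.0
        deltas = np.linspace(0.0, dmax, params.n_delta)

        fdr_grid = np.ones(params.n_delta)
        cutup_grid = np.full(params.n_delta, np.inf)
        cutlow_grid = np.full(params.n_delta, -np.inf)
        n_called_grid = np.zeros(params.n_delta, dtype=int)
        for k, delta in enumerate(deltas):
            up = np.nonzero(diff >= delta)[0]
            up = up[d_sorted[up] >= 0]  # upper cut lives on the positive side
            lo = np.nonzero(-diff >= delta)[0]
            lo = lo[d_sorted[lo] <= 0]
            cutup = d_sorted[up[0]] if up.size else np.inf
            cutlow = d_sorted[lo[-1]] if lo.size else -np.inf
            called = np.count_nonzero((d_sorted >= cutup) | (d_sorted <= cutlow))
            false = np.count_nonzero((perm_sorted >= cutup) | (perm_sorted <= cutlow),
                                     axis=1)
            fdr = pi0 * np.median(false) / max(1, called)
            fdr_grid[k] = min(1.0, fdr)
            cutup_grid[k], cutlow_grid[k], n_called_grid[k] = cutup, cutlow, called
        # running minimum = "smallest FDR achieved at or below this Delta";
        # non-increasing in Delta and exactly the q-value convention
        fdr_grid = np.minimum.accumulate(fdr_grid)

        ok = np.nonzero(fdr_grid <= params.fdr_target)[0]
        k_star = int(ok[0]) if ok.size else params.n_delta - 1
        delta_star = float(deltas[k_star])
        cutup_star, cutlow_star = cutup_grid[k_star], cutlow_grid[k_star]
        called = ((d >= cutup_star) | (d <= cutlow_star)) if ok.size \
            else np.zeros(m, dtype=bool)

        # q_i = FDR at the largest Delta still calling gene i
        q = np.ones(m)
        for i in range(m):
            ki = np.nonzero((d[i] >= cutup_grid) | (d[i] <= cutlow_grid))[0]
            if ki.size:
                q[i] = fdr_grid[ki[-1]]
        q = np.clip(q, 0.0, 1.0)

        fc = 2.0 ** r
        fc = np.where(fc >= 1.0, fc, -1.0 / fc)
        table = pd.DataFrame({
            "r": r, "s": s, "d": d, "fold_change": fc, "q": q, "called": called,
        }, index=genes)
        return SAMResults(model=self, params=params, table=table, s0=float(s0),
                          delta=delta_star, pi0=float(pi0),
                          expected_order_stats=dbar, exact_permutations=exact,
                          n_permutations_used=B, fdr_grid=fdr_grid,
                          delta_grid=deltas)


@dataclass
class SAMResults:
    """Fitted SAM run: per-gene table plus the global nuisance estimates."""

    model: SAM
    params: SamParams
    table: pd.DataFrame
    s0: float
    delta: float
    pi0: float
    expected_order_stats: np.ndarray
    exact_permutations: bool
    n_permutations_used: int
    fdr_grid: np.ndarray = field(repr=False, default=None)
    delta_grid: np.ndarray = field(repr=False, default=None)

    @property
    def called_genes(self) -> list:
        t = self.table[self.table["called"]]
        return list(t.reindex(t["d"].abs().sort_values(ascending=False).index).index)

    @property
    def n_called(self) -> int:
        return int(self.table["called"].sum())

    def summary(self) -> str:
        ref, test = self.model.group_order
        lines = [
            "Significance Analysis of Microarrays (two-class unpaired)",
            "=" * 60,
            f"groups: {test} vs {ref}   genes: {len(self.table)}   "
            f"samples: {self.model.matrix.n_samples}",
            f"permutations: {self.n_permutations_used}"
            f"{' (exact enumeration)' if self.exact_permutations else ''}",
            f"s0 = {self.s0:.4g}   pi0 = {self.pi0:.3f}   "
            f"delta = {self.delta:.4g}   FDR target = {self.params.fdr_target:g}",
            f"genes called: {self.n_called}",
            "-" * 60,
        ]
        top = self.table.reindex(
            self.table["d"].abs().sort_values(ascending=False).index).head(15)
        lines.append(f"{'gene':<12}{'d':>9}{'fold':>8}{'q':>10}  called")
        for g, row in top.iterrows():
            lines.append(f"{str(g):<12}{row['d']:>9.3f}{row['fold_change']:>8.2f}"
                         f"{row['q']:>10.3g}  {'*' if row['called'] else ''}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def sam_two_class(matrix: ExpressionMatrix, group_order=None,
                  params: SamParams | None = None) -> SAMResults:
    """Functional wrapper over ``SAM(matrix, group_order).fit(params)``."""
    return SAM(matrix, group_order).fit(params)
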