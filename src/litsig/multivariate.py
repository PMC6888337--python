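"""Sample-space PCA on signature genes, axis/group discrimination and
clustering misclassification.

Samples are the observations, genes the variables; variables are centered
and (by default) scaled to unit variance, so the decomposition is that of
the gene correlation matrix.  The first-axis group p-value is a one-way
ANOVA of the axis coordinates across sample groups — the correlation-ratio
test FactoMineR uses to describe axes by categorical variables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .corpus import fdr_correct
from .errors import InvalidLabelsError, InvalidParameterError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["PCA", "PCAResults", "DiscriminationTest", "pca",
           "axis_group_significance", "axis_gene_contributors",
           "cluster_misclassification"]


class PCA:
    """Principal component analysis of samples on an expression matrix."""

    def __init__(self, matrix: ExpressionMatrix, scale_unit: bool = True):
        if matrix.n_genes < 2 or matrix.n_samples < 3:
            raise InvalidParameterError("PCA needs >= 2 genes and >= 3 samples")
        self.matrix = matrix
        self.scale_unit = scale_unit

    def fit(self) -> "PCAResults":
        # samples x genes
        x = self.matrix.values.to_numpy(dtype=float).T
        genes = np.array(self.matrix.values.index)
        sd = x.std(axis=0, ddof=0)
        dropped: list = []
        if self.scale_unit and (sd == 0).any():
            dropped = list(genes[sd == 0])
            warnings.warn(f"dropping {len(dropped)} zero-variance genes for "
                          "unit scaling", stacklevel=2)
            keep = sd > 0
            x, genes, sd = x[:, keep], genes[keep], sd[keep]
        z = x - x.mean(axis=0)
        if self.scale_unit:
            z = z / sd
        u, sv, vt = np.linalg.svd(z, full_matrices=False)
        # orient each axis so its largest-|loading| gene loads positively
        for k in range(vt.shape[0]):
            j = np.argmax(np.abs(vt[k]))
            if vt[k, j] < 0:
                vt[k] *= -1.0
                u[:, k] *= -1.0
        coords = u * sv
        eig = sv ** 2
        var_pct = 100.0 * eig / eig.sum() if eig.sum() > 0 else np.zeros_like(eig)
        axes = [f"axis{k + 1}" for k in range(len(sv))]
        return PCAResults(
            model=self,
            coordinates=pd.DataFrame(coords, index=self.matrix.samples, columns=axes),
            loadings=pd.DataFrame(vt.T, index=genes, columns=axes),
            variance_explained=pd.Series(var_pct, index=axes),
            standardized=pd.DataFrame(z, index=self.matrix.samples, columns=genes),
            dropped_genes=dropped,
        )


@dataclass
class PCAResults:
    """Sample coordinates, loadings and variance shares of a fitted PCA."""

    model: PCA
    coordinates: pd.DataFrame       # samples x axes
    loadings: pd.DataFrame          # genes x axes (right singular vectors)
    variance_explained: pd.Series   # percent per axis
    standardized: pd.DataFrame      # samples x genes, the decomposed table
    dropped_genes: list

    @property
    def groups(self) -> dict:
        return self.model.matrix.groups

    def axis(self, axis: int) -> np.ndarray:
        if not 1 <= axis <= self.coordinates.shape[1]:
            raise InvalidParameterError(f"axis {axis} not computed")
        return self.coordinates.iloc[:, axis - 1].to_numpy()

    def summary(self) -> str:
        lines = ["Principal component analysis", "=" * 40,
                 f"samples: {self.coordinates.shape[0]}   "
                 f"genes: {self.loadings.shape[0]}"
                 + (f"   ({len(self.dropped_genes)} dropped)" if self.dropped_genes else "")]
        for name, v in self.variance_explained.head(5).items():
            lines.append(f"{name}: {v:6.2f}% of variance")
        return "\n".join(lines)


def pca(matrix: ExpressionMatrix, scale_unit: bool = True) -> PCAResults:
    """Functional wrapper over ``PCA(matrix, scale_unit).fit()``."""
    return PCA(matrix, scale_unit).fit()


@dataclass
class DiscriminationTest:
    """One-way ANOVA of one PCA axis across sample groups."""

    axis: int
    eta_squared: float
    f_statistic: float
    p_value: float


def axis_group_significance(pca_result: PCAResults, groups: dict | None = None,
                            axis: int = 1) -> DiscriminationTest:
    """How well one axis separates the sample groups (eta^2, F, p)."""
    groups = groups if groups is not None else pca_result.groups
    coord = pca_result.axis(axis)
    labels = np.array([groups[s] for s in pca_result.coordinates.index])
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise InvalidLabelsError("need >= 2 groups for a discrimination test")
    parts = [coord[labels == g] for g in uniq]
    if any(len(p) < 2 for p in parts):
        raise InvalidLabelsError("each group needs >= 2 samples")
    f, p = stats.f_oneway(*parts)
    grand = coord.mean()
    ss_between = sum(len(part) * (part.mean() - grand) ** 2 for part in parts)
    ss_total = ((coord - grand) ** 2).sum()
    eta2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
    return DiscriminationTest(axis=axis, eta_squared=eta2,
                              f_statistic=float(f), p_value=float(p))


def axis_gene_contributors(pca_result: PCAResults, axis: int = 1,
                           q_threshold: float = 0.05) -> list:
    """Genes whose standardized expression correlates with the axis
    coordinates at BH q < threshold, ranked by |correlation|."""
    coord = pca_result.axis(axis)
    z = pca_result.standardized
    n = len(coord)
    cc = coord - coord.mean()
    denom = np.sqrt((cc ** 2).sum())
    rvals = np.zeros(z.shape[1])
    for j in range(z.shape[1]):
        gj = z.iloc[:, j].to_numpy()
        gj = gj - gj.mean()
        gd = np.sqrt((gj ** 2).sum())
        rvals[j] = (cc @ gj) / (denom * gd) if denom > 0 and gd > 0 else 0.0
    rvals = np.clip(rvals, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rvals * np.sqrt((n - 2) / np.maximum(1e-300, 1 - rvals ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rvals) >= 1.0, 0.0, p)
    q = fdr_correct(p)
    genes = np.array(z.columns)
    sig = q < q_threshold
    order = np.argsort(-np.abs(rvals[sig]), kind="stable")
    return list(genes[sig][order])


def cluster_misclassification(matrix: ExpressionMatrix, groups: dict | None = None,
                              method: str = "average",
                              metric: str = "correlation") -> float:
    """Misclassification rate of hierarchical sample clustering against the
    known groups.

    Samples are clustered with distance 1 - Pearson correlation (average
    linkage by default), the tree is cut into k = #groups clusters and the
    error is the minimum fraction of misassigned samples over all
    cluster -> group assignments (exhaustive for k <= 4, Hungarian above).
    """
    groups = groups if groups is not None else matrix.groups
    labels = np.array([groups[s] for s in matrix.values.columns])
    uniq = list(pd.unique(labels))
    k = len(uniq)
    n = matrix.n_samples
    if k < 2:
        raise InvalidLabelsError("need >= 2 groups")
    if k > n:
        raise InvalidParameterError("more groups than samples")
    x = matrix.values.to_numpy(dtype=float).T  # samples x genes
    corr = np.corrcoef(x)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method=method)
    clusters = fcluster(link, t=k, criterion="maxclust")
    # contingency: clusters x groups
    cont = np.zeros((k, k), dtype=int)
    cl_ids = list(pd.unique(clusters))
    for ci, c in enumerate(cl_ids):
        for gi, g in enumerate(uniq):
            cont[ci, gi] = np.count_nonzero((clusters == c) & (labels == g))
    if k <= 4:
        best = max(sum(cont[i, perm[i]] for i in range(len(cl_ids)))
                   for perm in permutations(range(k)))
    else:
        ri, cj = linear_sum_assignment(-cont)
        best = cont[ri, cj].sum()
    return float(n - best) / n
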