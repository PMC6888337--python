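"""Literature gene x term co-occurrence evidence.

A :class:`CooccurrenceCorpus` holds how many documents mention each gene
symbol together with each query term (e.g. "lipids", "cholesterol",
"ceramides" in the NASH literature).  Genes are scored for
over-representation of their co-occurrence with a term set by a one-sided
hypergeometric test on the 2x2 document table, corrected by
Benjamini-Hochberg across genes; the q < 0.05 survivors form the signature
used to reduce the expression matrix.  A second pass ranks candidate genes
by their count on a primary term (e.g. "liver") for prioritization.

The hypergeometric + BH choice is a strategy hook (``score_fn`` argument of
:func:`score_gene_associations`): any callable mapping the 2x2 table margins
to a p-value can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    InconsistencyError,
    InvalidInputError,
    InvalidParameterError,
    KeyNotFoundError,
)

__all__ = [
    "CooccurrenceCorpus",
    "GeneAssociation",
    "PrioritizationTable",
    "query_cooccurrence",
    "score_gene_associations",
    "fdr_correct",
    "select_significant_genes",
    "prioritize_genes",
]


@dataclass
class CooccurrenceCorpus:
    """Gene x term document co-occurrence counts with a document total.

    ``counts`` is a genes x terms integer DataFrame; ``total_docs`` is the
    size of the document universe.  Gene symbols are matched
    case-insensitively (stored uppercased).
    """

    counts: pd.DataFrame
    total_docs: int

    def __post_init__(self) -> None:
        if self.total_docs <= 0:
            raise InvalidParameterError("total_docs must be positive")
        c = self.counts.copy()
        c.index = c.index.astype(str).str.upper()
        if c.index.has_duplicates:
            raise InvalidParameterError("duplicate gene symbols in corpus")
        if c.columns.has_duplicates:
            raise InvalidParameterError("duplicate terms in corpus")
        arr = c.to_numpy()
        if (arr < 0).any():
            raise InvalidParameterError("co-occurrence counts must be >= 0")
        self.counts = c.astype(int)
        marg = self.gene_marginals()
        if (marg > self.total_docs).any():
            g = marg.index[(marg > self.total_docs).to_numpy().nonzero()[0][0]]
            raise InconsistencyError(
                f"gene marginal of {g!r} exceeds total_docs={self.total_docs}")

    @property
    def genes(self) -> list:
        return list(self.counts.index)

    @property
    def terms(self) -> list:
        return list(self.counts.columns)

    def gene_marginals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def term_marginals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    # -- TSV dialect: long form, '#total_docs=' comment ----------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#total_docs={self.total_docs}\n")
            fh.write("gene\tterm\tcount\n")
            for g in self.counts.index:
                for t in self.counts.columns:
                    fh.write(f"{g}\t{t}\t{int(self.counts.at[g, t])}\n")

    @classmethod
    def from_tsv(cls, path) -> "CooccurrenceCorpus":
        total = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#total_docs="):
            total = int(first.strip().split("=", 1)[1])
        if total is None:
            raise InvalidInputError(f"{path}: missing '#total_docs=' header line")
        long = pd.read_csv(path, sep="\t", comment="#")
        wide = long.pivot_table(index="gene", columns="term", values="count",
                                fill_value=0, aggfunc="sum")
        wide.index.name = None
        wide.columns.name = None
        return cls(wide, total)


@dataclass
class GeneAssociation:
    """Per-gene literature association: summed count over the query terms,
    hypergeometric p and BH q."""

    gene: str
    count: int
    p_value: float
    q_value: float


@dataclass
class PrioritizationTable:
    """Top-k genes ranked by their primary-term count, with secondary-term
    counts retained (the circos-plot input)."""

    rows: pd.DataFrame  # columns: gene, term, count
    primary_term: str
    ranking: list

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def _resolve_gene(corpus: CooccurrenceCorpus, gene: str) -> str:
    g = str(gene).upper()
    if g not in corpus.counts.index:
        raise KeyNotFoundError(f"gene {gene!r} not in corpus")
    return g


def _resolve_terms(corpus: CooccurrenceCorpus, terms) -> list:
    out = []
    for t in terms:
        if t not in corpus.counts.columns:
            raise KeyNotFoundError(f"term {t!r} not in corpus")
        out.append(t)
    return out


def query_cooccurrence(corpus: CooccurrenceCorpus, gene: str, terms) -> int:
    """Summed co-occurrence count of ``gene`` over ``terms``."""
    g = _resolve_gene(corpus, gene)
    ts = _resolve_terms(corpus, terms)
    return int(corpus.counts.loc[g, ts].sum())


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order, clipped to [0,1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise InvalidInputError("NaN p-value passed to fdr_correct")
    if (p < 0).any() or (p > 1).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return np.clip(q, 0.0, 1.0)


def score_gene_associations(corpus: CooccurrenceCorpus, terms,
                            score_fn=None) -> list[GeneAssociation]:
    """Score every gene for over-represented co-occurrence with a term set.

    For gene g: k = documents mentioning g with any query term (summed
    counts), K = gene marginal, n = term-set marginal, N = total documents.
    p = P[X >= k], X ~ Hypergeom(N, K, n); BH q across genes.  Sorted by q
    ascending, ties by count descending then symbol.
    """
    if not list(terms):
        raise InvalidParameterError("terms must be non-empty")
    ts = _resolve_terms(corpus, terms)
    N = corpus.total_docs
    K = corpus.gene_marginals().to_numpy()
    n = int(corpus.term_marginals()[ts].sum())
    if n > N:
        raise InconsistencyError(f"term-set marginal {n} exceeds total_docs={N}")
    k = corpus.counts[ts].sum(axis=1).to_numpy()
    if score_fn is None:
        # survival function at k-1 gives P[X >= k]
        p = stats.hypergeom.sf(k - 1, N, K, n)
    else:
        p = np.array([score_fn(int(ki), int(Ki), n, N) for ki, Ki in zip(k, K)])
    p = np.clip(p, 0.0, 1.0)
    q = fdr_correct(p)
    assoc = [GeneAssociation(g, int(ki), float(pi), float(qi))
             for g, ki, pi, qi in zip(corpus.genes, k, p, q)]
    assoc.sort(key=lambda a: (a.q_value, -a.count, a.gene))
    return assoc


def select_significant_genes(associations, q_threshold: float = 0.05) -> list:
    """Genes with q < threshold, q-ascending (count desc, symbol as ties)."""
    sig = [a for a in associations if a.q_value < q_threshold]
    sig.sort(key=lambda a: (a.q_value, -a.count, a.gene))
    return [a.gene for a in sig]


def prioritize_genes(corpus: CooccurrenceCorpus, genes, primary_term: str,
                     secondary_terms, k: int) -> PrioritizationTable:
    """Rank ``genes`` by primary-term count (ties: total secondary count then
    symbol), keep the top k, and tabulate their secondary-term counts."""
    if k > len(list(genes)):
        raise InvalidParameterError("k exceeds the candidate gene list")
    pt = _resolve_terms(corpus, [primary_term])[0]
    sts = _resolve_terms(corpus, secondary_terms)
    resolved = [_resolve_gene(corpus, g) for g in genes]
    prim = {g: int(corpus.counts.at[g, pt]) for g in resolved}
    sec_tot = {g: int(corpus.counts.loc[g, sts].sum()) for g in resolved}
    ranking = sorted(resolved, key=lambda g: (-prim[g], -sec_tot[g], g))
    kept = ranking[:k]
    rows = []
    for g in kept:
        rows.append({"gene": g, "term": pt, "count": prim[g]})
        for t in sts:
            rows.append({"gene": g, "term": t, "count": int(corpus.counts.at[g, t])})
    return PrioritizationTable(pd.DataFrame(rows, columns=["gene", "term", "count"]),
                               pt, ranking)
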