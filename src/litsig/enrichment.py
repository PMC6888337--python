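"""Over-representation analysis of a gene list against annotation sets
(GO-BP / CTD-disease style), with enrichment Z-score, exact hypergeometric
p and BH correction, plus a bipartite gene-function network export.

The Z-score is the normal approximation to the hypergeometric overlap:

    z = (r - n R / N) / sqrt( n (R/N) (1 - R/N) (N - n)/(N - 1) )

with r the overlap, n the query size inside the universe, R the annotation
set size and N the universe size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import fdr_correct
from .errors import EmptyResultError, InvalidInputError

__all__ = ["AnnotationDB", "EnrichmentResult", "enrich",
           "export_enrichment_network", "read_gmt"]


@dataclass
class AnnotationDB:
    """Named gene sets over a gene universe (symbols uppercased)."""

    sets: dict            # term -> set of symbols
    universe: set

    def __post_init__(self) -> None:
        if not self.universe:
            raise InvalidInputError("annotation universe is empty")
        self.universe = {str(g).upper() for g in self.universe}
        clean = {}
        for term, genes in self.sets.items():
            gs = {str(g).upper() for g in genes} & self.universe
            if not term:
                raise InvalidInputError("empty term name in annotation DB")
            clean[term] = gs
        self.sets = clean

    def restrict_universe(self, genes) -> "AnnotationDB":
        """Intersect the universe (and every set) with measured genes."""
        uni = self.universe & {str(g).upper() for g in genes}
        if not uni:
            raise EmptyResultError("no annotated gene is measured")
        return AnnotationDB({t: s & uni for t, s in self.sets.items()}, uni)


def read_gmt(path) -> AnnotationDB:
    """Read GMT (term <TAB> description <TAB> gene...); universe = union."""
    sets: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    if not sets:
        raise InvalidInputError(f"{path}: no gene sets found")
    universe = set().union(*sets.values())
    return AnnotationDB(sets, universe)


def write_gmt(db: AnnotationDB, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(db.sets):
            genes = "\t".join(sorted(db.sets[term]))
            fh.write(f"{term}\tna\t{genes}\n")


@dataclass
class EnrichmentResult:
    term: str
    overlap_genes: list
    r: int          # overlap size
    n: int          # query size within universe
    R: int          # set size
    N: int          # universe size
    z_score: float
    p_value: float
    q_value: float


def enrich(query, db: AnnotationDB) -> list[EnrichmentResult]:
    """Score every annotation set for over-representation in ``query``.

    Results carry z, exact one-sided hypergeometric p and BH q; sorted by z
    descending (ties: term name).
    """
    q_genes = {str(g).upper() for g in query} & db.universe
    if not q_genes:
        raise EmptyResultError("query does not intersect the annotation universe")
    N = len(db.universe)
    n = len(q_genes)
    out = []
    pvals = []
    for term in sorted(db.sets):
        genes = db.sets[term]
        R = len(genes)
        overlap = sorted(q_genes & genes)
        r = len(overlap)
        if 0 < R < N:
            mu = n * R / N
            var = n * (R / N) * (1 - R / N) * ((N - n) / (N - 1))
            z = (r - mu) / np.sqrt(var) if var > 0 else 0.0
        else:
            z = 0.0
        p = float(stats.hypergeom.sf(r - 1, N, R, n))
        pvals.append(min(1.0, p))
        out.append(EnrichmentResult(term, overlap, r, n, R, N, float(z), p, 1.0))
    qvals = fdr_correct(pvals)
    for res, qv in zip(out, qvals):
        res.q_value = float(qv)
    out.sort(key=lambda e: (-e.z_score, e.term))
    return out


def export_enrichment_network(results, q_threshold: float = 0.05):
    """Bipartite gene-function tables for significant terms.

    Returns ``(edges, nodes)``: edges (source gene, target term, type) for
    every overlap gene of every term with q < threshold; nodes with type
    gene|function and z for functions.  Both write directly as edge-list
    TSVs loadable by Cytoscape-class tools.
    """
    edges = []
    nodes: dict = {}
    for res in results:
        if res.q_value >= q_threshold:
            continue
        nodes[res.term] = {"node": res.term, "type": "function", "z": res.z_score}
        for g in res.overlap_genes:
            edges.append({"source": g, "target": res.term, "type": "gene-function"})
            nodes.setdefault(g, {"node": g, "type": "gene", "z": np.nan})
    edge_df = pd.DataFrame(edges, columns=["source", "target", "type"])
    node_df = pd.DataFrame(list(nodes.values()), columns=["node", "type", "z"])
    return edge_df, node_df


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "term": e.term, "r": e.r, "n": e.n, "R": e.R, "N": e.N,
        "z": e.z_score, "p": e.p_value, "q": e.q_value,
        "overlap": ",".join(e.overlap_genes),
    } for e in results])
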