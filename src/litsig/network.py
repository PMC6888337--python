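"""Protein-interaction networks: TSV ingestion and first-neighbor expansion
of a seed gene (the partner set fed to the second SAM pass)."""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .errors import FormatError, KeyNotFoundError

logger = logging.getLogger(__name__)

__all__ = ["InteractionNetwork", "read_interactions", "partner_expansion"]


class InteractionNetwork:
    """Undirected, deduplicated, self-loop-free interaction graph over
    uppercased gene symbols."""

    def __init__(self, edges) -> None:
        g = nx.Graph()
        n_self = n_dup = 0
        for a, b in edges:
            a, b = str(a).upper().strip(), str(b).upper().strip()
            if not a or not b:
                continue
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
        if n_self or n_dup:
            logger.info("interaction ingest: dropped %d self-loops, %d duplicates",
                        n_self, n_dup)
        self.graph = g
        self.n_self_loops_dropped = n_self
        self.n_duplicates_dropped = n_dup

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_node(self, symbol: str) -> None:
        self.graph.add_node(str(symbol).upper())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("interactor_a\tinteractor_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{a}\t{b}\n")


def read_interactions(path) -> InteractionNetwork:
    """Read a two-column (or wider; extras ignored) interactor TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: interaction table needs >= 2 columns")
    pairs = df.iloc[:, :2].dropna().itertuples(index=False, name=None)
    return InteractionNetwork(pairs)


def partner_expansion(net: InteractionNetwork, seed: str, depth: int = 1) -> list:
    """All neighbors of ``seed`` within ``depth`` hops, lexicographically
    ordered, seed excluded."""
    s = str(seed).upper()
    if s not in net.graph:
        raise KeyNotFoundError(f"seed {seed!r} not in the interaction network")
    reach = {s}
    frontier = {s}
    for _ in range(depth):
        frontier = {n for f in frontier for n in net.graph.neighbors(f)} - reach
        reach |= frontier
    return sorted(reach - {s})
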