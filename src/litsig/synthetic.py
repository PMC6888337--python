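"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator draws from a simple, explicitly stated model chosen so that
the downstream statistic is exact or well calibrated under the null:

* corpus — Poisson counts under gene x term independence (rate =
  product of marginals / total), with planted gene-term associations whose
  rate is multiplied by an enrichment factor;
* expression — Gaussian noise on the log2 scale around group means, a
  designated group shifted by +-effect on a known DE subset (the regime of
  RMA-normalized microarray data);
* network — Erdos-Renyi background edges plus a guaranteed hub-partner
  star;
* survival — Bernoulli per-gene alterations and exponential event times
  whose hazard is multiplied by a known ratio for patients altered in a
  core gene, with independent exponential censoring.

All generators take one seed and are bit-reproducible; no global RNG state
is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import CooccurrenceCorpus
from .enrichment import AnnotationDB
from .errors import InvalidParameterError
from .expression import ExpressionMatrix
from .network import InteractionNetwork
from .survival import AlterationProfile, SurvivalRecord

__all__ = ["SyntheticTruth", "synth_corpus", "synth_expression",
           "synth_network", "synth_survival_alterations", "synth_annotation"]


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators.

    ``de_genes`` maps gene -> signed log2 effect; the other fields are
    plain sets (plus the survival hazard ratio).
    """

    associated_genes: set = field(default_factory=set)
    de_genes: dict = field(default_factory=dict)
    partner_genes: set = field(default_factory=set)
    altered_core_genes: set = field(default_factory=set)
    hazard_ratio: float = 1.0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("entity\trole\teffect\n")
            for g in sorted(self.associated_genes):
                fh.write(f"{g}\tassociated\t\n")
            for g in sorted(self.de_genes):
                fh.write(f"{g}\tde\t{self.de_genes[g]:g}\n")
            for g in sorted(self.partner_genes):
                fh.write(f"{g}\tpartner\t\n")
            for g in sorted(self.altered_core_genes):
                fh.write(f"{g}\taltered_core\t\n")
            fh.write(f"__hazard_ratio__\thazard_ratio\t{self.hazard_ratio:g}\n")


def _gene_names(n: int, prefix: str = "G") -> list:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


BACKGROUND_TERM = "background"


def synth_corpus(n_genes: int, n_terms: int, n_assoc: int,
                 enrichment_factor: float, total_docs: int,
                 seed: int) -> tuple[CooccurrenceCorpus, SyntheticTruth]:
    """Gene x term Poisson co-occurrence counts with planted associations.

    The table holds ``n_terms`` query terms plus one ``background`` column
    standing for each gene's remaining literature presence, so a gene's row
    sum is its full document count (as a real PubMed marginal would be).
    Under the null, count(g, t) ~ Poisson(total_docs * p_g * q_t) with
    heavy-tailed gene weights p and term weights q; for the ``n_assoc``
    associated genes the rate on every *query* term is multiplied by
    ``enrichment_factor``, emulating genes whose lipid-term co-occurrence
    exceeds what their overall literature presence predicts.  Query the
    scorer with the non-background terms (:func:`query_terms`).
    """
    if n_genes <= 0 or n_terms <= 0 or n_assoc < 0:
        raise InvalidParameterError("sizes must be positive")
    if n_assoc > n_genes:
        raise InvalidParameterError("n_assoc exceeds n_genes")
    if enrichment_factor <= 1:
        raise InvalidParameterError("enrichment_factor must be > 1")
    if total_docs <= 0:
        raise InvalidParameterError("total_docs must be positive")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    terms = [f"term{j}" for j in range(1, n_terms + 1)]
    gene_w = np.exp(rng.uniform(np.log(5), np.log(200), size=n_genes))
    p_g = gene_w / gene_w.sum()
    term_w = np.exp(rng.uniform(np.log(1.0), np.log(4.0), size=n_terms))
    # query terms carry ~20% of the literature, the background the rest
    q_t = np.append(0.2 * term_w / term_w.sum(), 0.8)
    rate = total_docs * np.outer(p_g, q_t)
    assoc_idx = np.sort(rng.choice(n_genes, size=n_assoc, replace=False)) \
        if n_assoc else np.array([], dtype=int)
    rate[assoc_idx, :n_terms] *= enrichment_factor
    counts = rng.poisson(rate)
    total = max(total_docs, int(counts.sum()) + 1)
    corpus = CooccurrenceCorpus(
        pd.DataFrame(counts, index=genes, columns=terms + [BACKGROUND_TERM]),
        total)
    truth = SyntheticTruth(associated_genes={genes[i] for i in assoc_idx})
    return corpus, truth


def query_terms(corpus: CooccurrenceCorpus) -> list:
    """The non-background terms of a synthetic (or compatible) corpus."""
    return [t for t in corpus.terms if t != BACKGROUND_TERM]


def synth_expression(n_genes: int, group_sizes, n_de: int, effect: float,
                     sigma: float, seed: int,
                     group_names=None) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Log2 expression with a known DE subset shifted in the second group.

    values = gene baseline + shift + N(0, sigma^2); for DE genes the second
    group is shifted by a signed effect (sign drawn per gene).  With
    ``effect=0`` the truth genes are genuine nulls.
    """
    group_sizes = list(group_sizes)
    if n_de > n_genes:
        raise InvalidParameterError("n_de exceeds n_genes")
    if len(group_sizes) < 2:
        raise InvalidParameterError("need >= 2 groups")
    if any(g < 2 for g in group_sizes):
        raise InvalidParameterError("each group needs >= 2 samples")
    if sigma <= 0:
        raise InvalidParameterError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    if group_names is None:
        group_names = [f"grp{chr(ord('A') + i)}" for i in range(len(group_sizes))]
    baseline = rng.uniform(5.0, 10.0, size=n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    n_total = sum(group_sizes)
    x = baseline[:, None] + rng.normal(0.0, sigma, size=(n_genes, n_total))
    # the second group carries the DE shift
    start = group_sizes[0]
    stop = start + group_sizes[1]
    if effect != 0:
        x[de_idx, start:stop] += (signs * effect)[:, None]
    samples, groups = [], {}
    i = 0
    for gname, size in zip(group_names, group_sizes):
        for j in range(size):
            sid = f"S{i + 1:03d}"
            samples.append(sid)
            groups[sid] = gname
            i += 1
    matrix = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), groups)
    truth = SyntheticTruth(
        de_genes={genes[i]: float(s * effect) for i, s in zip(de_idx, signs)}
        if effect != 0 else {genes[i]: 0.0 for i in de_idx})
    return matrix, truth


def synth_network(n_nodes: int, p_edge: float, hub: str, n_partners: int,
                  seed: int) -> tuple[InteractionNetwork, SyntheticTruth]:
    """Erdos-Renyi background plus a guaranteed hub-partner star."""
    if not 0 <= p_edge <= 1:
        raise InvalidParameterError("p_edge must lie in [0, 1]")
    if n_partners >= n_nodes:
        raise InvalidParameterError("n_partners must be < n_nodes")
    rng = np.random.default_rng(seed)
    others = _gene_names(n_nodes - 1, prefix="N")
    hub = str(hub).upper()
    if hub in others:
        raise InvalidParameterError(f"hub {hub!r} collides with generated names")
    nodes = [hub] + others
    partner_idx = rng.choice(len(others), size=n_partners, replace=False)
    partners = {others[i] for i in partner_idx}
    edges = [(hub, p) for p in sorted(partners)]
    n = len(nodes)
    if p_edge > 0:
        mask = rng.random((n, n)) < p_edge
        for i in range(n):
            for j in range(i + 1, n):
                if mask[i, j]:
                    edges.append((nodes[i], nodes[j]))
    net = InteractionNetwork(edges)
    for node in nodes:   # isolated nodes still belong to the universe
        net.add_node(node)
    return net, SyntheticTruth(partner_genes=partners)


def synth_survival_alterations(n_patients: int, genes, alt_rates,
                               core_genes, hazard_ratio: float,
                               baseline_hazard: float, censor_rate: float,
                               seed: int):
    """Bernoulli alterations + exponential survival with a core-gene hazard.

    Event time ~ Exp(h) with h = baseline_hazard * hazard_ratio for
    patients altered in >= 1 core gene, else baseline_hazard.  Censoring is
    an independent exponential whose rate gives a baseline patient
    censoring probability of ``censor_rate`` (0 -> none, 1 -> everyone
    censored at the drawn time).
    """
    genes = [str(g).upper() for g in genes]
    if not genes:
        raise InvalidParameterError("gene list is empty")
    rates = np.asarray(alt_rates, dtype=float)
    if rates.shape != (len(genes),):
        raise InvalidParameterError("alt_rates must align with genes")
    if ((rates < 0) | (rates > 1)).any() or not 0 <= censor_rate <= 1:
        raise InvalidParameterError("rates must lie in [0, 1]")
    if hazard_ratio <= 0 or baseline_hazard <= 0:
        raise InvalidParameterError("hazards must be positive")
    core = {str(g).upper() for g in core_genes}
    rng = np.random.default_rng(seed)
    patients = [f"P{i:04d}" for i in range(1, n_patients + 1)]
    calls = rng.random((n_patients, len(genes))) < rates
    classes = {}
    class_draw = rng.choice(["mutation", "amplification", "deletion"],
                            size=calls.shape)
    for i, p in enumerate(patients):
        for j, g in enumerate(genes):
            if calls[i, j]:
                classes[(p, g)] = str(class_draw[i, j])
    profile = AlterationProfile(
        pd.DataFrame(calls, index=patients, columns=genes), classes)
    core_mask = calls[:, [j for j, g in enumerate(genes) if g in core]].any(axis=1) \
        if core else np.zeros(n_patients, dtype=bool)
    hazard = np.where(core_mask, baseline_hazard * hazard_ratio, baseline_hazard)
    event_t = rng.exponential(1.0 / hazard)
    records = []
    if censor_rate >= 1.0:
        for p, t in zip(patients, event_t):
            records.append(SurvivalRecord(p, float(t), 0))
    elif censor_rate <= 0.0:
        for p, t in zip(patients, event_t):
            records.append(SurvivalRecord(p, float(t), 1))
    else:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        censor_t = rng.exponential(1.0 / c_rate, size=n_patients)
        for p, t, c in zip(patients, event_t, censor_t):
            records.append(SurvivalRecord(p, float(min(t, c)), int(t <= c)))
    truth = SyntheticTruth(altered_core_genes=set(core) & set(genes),
                           hazard_ratio=float(hazard_ratio))
    return profile, records, truth


def synth_annotation(truth_genes, universe, n_decoy_sets: int, set_size: int,
                     seed: int, truth_term: str = "planted_set") -> AnnotationDB:
    """Annotation DB holding the truth set plus random decoy sets; the
    end-to-end pipeline's enrichment stage input."""
    universe = [str(g).upper() for g in universe]
    truth_set = {str(g).upper() for g in truth_genes} & set(universe)
    if not truth_set:
        raise InvalidParameterError("truth genes must intersect the universe")
    rng = np.random.default_rng(seed)
    sets = {truth_term: truth_set}
    for i in range(1, n_decoy_sets + 1):
        size = min(set_size, len(universe))
        sets[f"decoy{i:03d}"] = set(rng.choice(universe, size=size, replace=False))
    return AnnotationDB(sets, set(universe))
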