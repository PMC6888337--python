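"""End-to-end orchestration of the literature-to-survival workflow.

Stage order mirrors the analysis workflow: text-mining scoring -> FDR gene
selection -> matrix reduction -> SAM -> PCA/clustering -> enrichment ->
prioritization -> interaction-partner expansion -> second SAM -> alteration
survival stratification.  Every stage writes TSV artifacts plus a manifest
(sha256 of inputs, parameters, outputs); a stage re-runs only when its
inputs, parameters or outputs changed on disk.

``synth_bundle`` writes a coherent synthetic input set over one gene
universe: the literature-associated genes contain the differentially
expressed genes, the interaction hub's partners overlap them, and the
high-alteration-rate core genes are drawn from them, so the full run has a
recoverable ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corpus as corpus_mod
from . import enrichment as enr_mod
from . import markers as markers_mod
from . import multivariate as mv_mod
from . import network as net_mod
from . import survival as surv_mod
from .errors import InvalidParameterError, LitsigError
from .expression import ExpressionMatrix, reduce_to_signature
from .sam import SamParams, sam_two_class
from .synthetic import (
    SyntheticTruth,
    query_terms,
    synth_annotation,
    synth_corpus,
    synth_expression,
    synth_network,
    synth_survival_alterations,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "synth_bundle"]

DEFAULT_SYNTH = {
    # mirrors the study conditions: 87 literature-selected genes of which 25
    # are differentially expressed, 24/24/23 sample groups, a 353-patient
    # alteration cohort with a 5-gene >=4% core
    "n_genes": 500, "n_terms": 6, "n_assoc": 87, "enrichment_factor": 8.0,
    "total_docs": 100_000,
    "group_sizes": [24, 24, 23], "group_names": ["HO", "NASH", "NAFL"],
    "n_de": 25, "effect": 1.0, "sigma": 0.5,
    "n_nodes": 300, "p_edge": 0.01, "hub": "HUB1", "n_partners": 40,
    "n_patients": 353, "n_alt_genes": 30, "n_core": 5,
    "core_rate": 0.08, "background_rate": 0.01,
    "hazard_ratio": 4.0, "baseline_hazard": 0.02, "censor_rate": 0.3,
    "n_decoy_sets": 30, "decoy_set_size": 25,
}


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds of one pipeline run."""

    out_dir: str = "litsig_run"
    seed: int = 0
    synthetic: dict | None = None          # None -> use paths below
    paths: dict = field(default_factory=dict)
    q_text: float = 0.05
    fdr_sam: float = 0.05
    q_axis: float = 0.05
    alt_threshold: float = 0.04
    sam_permutations: int = 500
    group_pair: tuple | None = None        # (reference, test) for SAM
    primary_term: str | None = None
    prioritize_k: int = 10
    hub: str | None = None
    stages: list = field(default_factory=lambda: [
        "simulate", "mine", "reduce", "sam", "pca", "markers", "enrich",
        "prioritize", "partners", "survival"])

    def __post_init__(self) -> None:
        for name in ("q_text", "fdr_sam", "q_axis", "alt_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidParameterError(f"{name}={v} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "group_pair" in raw and raw["group_pair"] is not None:
            raw["group_pair"] = tuple(raw["group_pair"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# stage caching
# ---------------------------------------------------------------------------

def _sha(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(run_dir: Path, name: str, inputs: list, params: dict,
           outputs: list, fn) -> bool:
    """Run ``fn`` unless the recorded manifest still matches; returns True
    when the stage executed."""
    manifest_path = run_dir / f"{name}.manifest.json"
    want = {
        "stage": name,
        "params": params,
        "inputs": {str(p): _sha(Path(p)) for p in inputs},
    }
    if manifest_path.exists():
        try:
            have = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            have = None
        if (have and have.get("params") == want["params"]
                and have.get("inputs") == want["inputs"]
                and all(Path(o).exists() for o in outputs)
                and have.get("outputs") == {
                    str(o): _sha(Path(o)) for o in outputs}):
            logger.info("stage %s: cache hit, skipped", name)
            return False
    try:
        fn()
    except LitsigError:
        logger.error("stage %s failed; artifacts so far kept in %s", name, run_dir)
        raise
    want["outputs"] = {str(o): _sha(Path(o)) for o in outputs}
    manifest_path.write_text(json.dumps(want, indent=1, sort_keys=True))
    return True


# ---------------------------------------------------------------------------
# synthetic bundle
# ---------------------------------------------------------------------------

def _relabel(names_from: list, truth_subset, names_to_truth: list,
             all_names: list) -> dict:
    """Deterministic bijection sending ``truth_subset`` onto the head of
    ``names_to_truth`` and everything else onto the remaining names."""
    truth_sorted = sorted(truth_subset)
    targets = list(names_to_truth)[:len(truth_sorted)]
    mapping = dict(zip(truth_sorted, targets))
    rest_from = [g for g in names_from if g not in mapping]
    rest_to = [g for g in all_names if g not in set(targets)]
    mapping.update(zip(rest_from, rest_to))
    return mapping


def synth_bundle(config: PipelineConfig, out_dir: Path) -> SyntheticTruth:
    """Write a coherent synthetic input bundle and its ground truth."""
    p = dict(DEFAULT_SYNTH)
    p.update(config.synthetic or {})
    seed = config.seed
    out_dir.mkdir(parents=True, exist_ok=True)

    corpus, c_truth = synth_corpus(p["n_genes"], p["n_terms"], p["n_assoc"],
                                   p["enrichment_factor"], p["total_docs"], seed)
    genes = corpus.genes
    assoc = sorted(c_truth.associated_genes)

    expr, e_truth = synth_expression(p["n_genes"], p["group_sizes"], p["n_de"],
                                     p["effect"], p["sigma"], seed + 1,
                                     group_names=p["group_names"])
    # relabel so the DE genes sit inside the literature-associated set
    mapping = _relabel(list(expr.values.index), set(e_truth.de_genes), assoc, genes)
    values = expr.values.copy()
    values.index = [mapping[g] for g in values.index]
    values = values.sort_index()
    expr = ExpressionMatrix(values, expr.groups)
    de_genes = {mapping[g]: eff for g, eff in e_truth.de_genes.items()}

    net, n_truth = synth_network(p["n_nodes"], p["p_edge"], p["hub"],
                                 p["n_partners"], seed + 2)
    # partners land on DE genes first, then on other measured genes
    de_sorted = sorted(de_genes)
    other = [g for g in genes if g not in de_genes]
    net_map = _relabel([n for n in net.nodes if n != p["hub"].upper()],
                       n_truth.partner_genes, de_sorted + other, genes)
    net_map[p["hub"].upper()] = p["hub"].upper()
    relabeled = net_mod.InteractionNetwork(
        (net_map[a], net_map[b]) for a, b in net.graph.edges)
    for node in net.nodes:
        relabeled.add_node(net_map[node])
    partners = {net_map[g] for g in n_truth.partner_genes}

    n_alt = min(p["n_alt_genes"], len(genes))
    alt_genes = de_sorted[:n_alt] + other[:max(0, n_alt - len(de_sorted))]
    core = de_sorted[:p["n_core"]]
    rates = np.where(np.isin(sorted(alt_genes), core),
                     p["core_rate"], p["background_rate"])
    profile, records, s_truth = synth_survival_alterations(
        p["n_patients"], sorted(alt_genes), rates, core, p["hazard_ratio"],
        p["baseline_hazard"], p["censor_rate"], seed + 3)

    db = synth_annotation(de_genes, genes, p["n_decoy_sets"],
                          p["decoy_set_size"], seed + 4)

    truth = SyntheticTruth(associated_genes=set(assoc), de_genes=de_genes,
                           partner_genes=partners,
                           altered_core_genes=set(core),
                           hazard_ratio=p["hazard_ratio"])

    corpus.to_tsv(out_dir / "corpus.tsv")
    expr.to_tsv(out_dir / "matrix.tsv")
    pd.Series(expr.groups, name="group").rename_axis("sample") \
        .to_csv(out_dir / "groups.tsv", sep="\t")
    relabeled.to_tsv(out_dir / "interactions.tsv")
    profile.to_tsv(out_dir / "alterations.tsv")
    surv_mod.records_to_tsv(records, out_dir / "survival.tsv")
    enr_mod.write_gmt(db, out_dir / "annotation.gmt")
    truth.to_tsv(out_dir / "truth.tsv")
    return truth


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _load_matrix(paths: dict) -> ExpressionMatrix:
    groups = pd.read_csv(paths["groups"], sep="\t", index_col=0)["group"].to_dict()
    return ExpressionMatrix.from_tsv(paths["matrix"], groups)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    paths = dict(config.paths)

    if "simulate" in config.stages and config.synthetic is not None:
        data_dir = run_dir / "inputs"
        synth_params = {**DEFAULT_SYNTH, **(config.synthetic or {}),
                        "seed": config.seed}
        outputs = [data_dir / n for n in
                   ("corpus.tsv", "matrix.tsv", "groups.tsv", "interactions.tsv",
                    "alterations.tsv", "survival.tsv", "annotation.gmt",
                    "truth.tsv")]
        _stage(run_dir, "simulate", [], synth_params, outputs,
               lambda: synth_bundle(config, data_dir))
        paths.setdefault("corpus", str(data_dir / "corpus.tsv"))
        paths.setdefault("matrix", str(data_dir / "matrix.tsv"))
        paths.setdefault("groups", str(data_dir / "groups.tsv"))
        paths.setdefault("interactions", str(data_dir / "interactions.tsv"))
        paths.setdefault("alterations", str(data_dir / "alterations.tsv"))
        paths.setdefault("survival", str(data_dir / "survival.tsv"))
        paths.setdefault("annotation", str(data_dir / "annotation.gmt"))
        if config.group_pair is None:
            # reference vs the designated (shifted) group of the generator
            names = synth_params["group_names"]
            config.group_pair = (names[0], names[1])

    # -- mine ---------------------------------------------------------------
    assoc_tsv = run_dir / "associations.tsv"
    selected_txt = run_dir / "selected_genes.txt"
    if "mine" in config.stages:
        def mine():
            corp = corpus_mod.CooccurrenceCorpus.from_tsv(paths["corpus"])
            assoc = corpus_mod.score_gene_associations(corp, query_terms(corp))
            pd.DataFrame([a.__dict__ for a in assoc]) \
                .to_csv(assoc_tsv, sep="\t", index=False, float_format="%.10g")
            sel = corpus_mod.select_significant_genes(assoc, config.q_text)
            selected_txt.write_text("\n".join(sel) + "\n")
        _stage(run_dir, "mine", [paths["corpus"]], {"q_text": config.q_text},
               [assoc_tsv, selected_txt], mine)

    # -- reduce -------------------------------------------------------------
    reduced_tsv = run_dir / "reduced_matrix.tsv"
    if "reduce" in config.stages:
        def reduce_stage():
            matrix = _load_matrix(paths)
            sel = selected_txt.read_text().split()
            reduce_to_signature(matrix, sel).to_tsv(reduced_tsv)
        _stage(run_dir, "reduce",
               [paths["matrix"], paths["groups"], selected_txt], {},
               [reduced_tsv], reduce_stage)

    # -- sam ----------------------------------------------------------------
    sam_tsv = run_dir / "sam_result.tsv"
    called_txt = run_dir / "sam_called.txt"
    sam_params = {"fdr": config.fdr_sam, "seed": config.seed,
                  "n_permutations": config.sam_permutations,
                  "group_pair": list(config.group_pair) if config.group_pair else None}
    if "sam" in config.stages:
        def sam_stage():
            matrix = ExpressionMatrix.from_tsv(
                reduced_tsv,
                pd.read_csv(paths["groups"], sep="\t", index_col=0)["group"].to_dict())
            pair = config.group_pair or tuple(sorted(matrix.group_labels())[:2])
            two = matrix.subset_groups(list(pair))
            res = sam_two_class(two, pair, SamParams(
                n_permutations=config.sam_permutations,
                fdr_target=config.fdr_sam, seed=config.seed))
            res.to_tsv(sam_tsv)
            called_txt.write_text("\n".join(res.called_genes) + "\n")
        _stage(run_dir, "sam", [reduced_tsv, paths["groups"]], sam_params,
               [sam_tsv, called_txt], sam_stage)

    # -- pca ----------------------------------------------------------------
    pca_json = run_dir / "pca_summary.json"
    coords_tsv = run_dir / "pca_coordinates.tsv"
    if "pca" in config.stages:
        def pca_stage():
            matrix = ExpressionMatrix.from_tsv(
                reduced_tsv,
                pd.read_csv(paths["groups"], sep="\t", index_col=0)["group"].to_dict())
            res = mv_mod.pca(matrix)
            res.coordinates.to_csv(coords_tsv, sep="\t", float_format="%.10g")
            test = mv_mod.axis_group_significance(res, axis=1)
            contrib = mv_mod.axis_gene_contributors(res, 1, config.q_axis)
            err = mv_mod.cluster_misclassification(matrix)
            pca_json.write_text(json.dumps({
                "axis1_p": test.p_value, "axis1_eta2": test.eta_squared,
                "axis1_F": test.f_statistic,
                "variance_pct": list(res.variance_explained[:5]),
                "axis1_contributors": contrib,
                "misclassification_rate": err,
            }, indent=1))
        _stage(run_dir, "pca", [reduced_tsv, paths["groups"]],
               {"q_axis": config.q_axis}, [pca_json, coords_tsv], pca_stage)

    # -- markers ------------------------------------------------------------
    markers_tsv = run_dir / "marker_report.tsv"
    if "markers" in config.stages:
        def markers_stage():
            matrix = ExpressionMatrix.from_tsv(
                reduced_tsv,
                pd.read_csv(paths["groups"], sep="\t", index_col=0)["group"].to_dict())
            pair = config.group_pair or tuple(sorted(matrix.group_labels())[:2])
            called = called_txt.read_text().split()
            rep = markers_mod.marker_report(matrix, called, pair[1], pair[0])
            rep.to_csv(markers_tsv, sep="\t", index=False, float_format="%.10g")
        _stage(run_dir, "markers", [reduced_tsv, called_txt, paths["groups"]],
               {"group_pair": list(config.group_pair) if config.group_pair else None},
               [markers_tsv], markers_stage)

    # -- enrich -------------------------------------------------------------
    enrich_tsv = run_dir / "enrichment.tsv"
    if "enrich" in config.stages and "annotation" in paths:
        def enrich_stage():
            db = enr_mod.read_gmt(paths["annotation"])
            called = called_txt.read_text().split()
            results = enr_mod.enrich(called, db)
            enr_mod.results_table(results).to_csv(
                enrich_tsv, sep="\t", index=False, float_format="%.10g")
            edges, nodes = enr_mod.export_enrichment_network(results, 0.05)
            edges.to_csv(run_dir / "enrichment_edges.tsv", sep="\t", index=False)
            nodes.to_csv(run_dir / "enrichment_nodes.tsv", sep="\t", index=False,
                         float_format="%.10g")
        _stage(run_dir, "enrich", [called_txt, paths["annotation"]], {},
               [enrich_tsv], enrich_stage)

    # -- prioritize ---------------------------------------------------------
    prio_tsv = run_dir / "prioritization.tsv"
    if "prioritize" in config.stages:
        def prio_stage():
            corp = corpus_mod.CooccurrenceCorpus.from_tsv(paths["corpus"])
            called = called_txt.read_text().split()
            qts = query_terms(corp)
            primary = config.primary_term or qts[0]
            secondary = [t for t in qts if t != primary]
            k = min(config.prioritize_k, len(called))
            table = corpus_mod.prioritize_genes(corp, called, primary,
                                                secondary, k)
            table.to_tsv(prio_tsv)
        _stage(run_dir, "prioritize", [paths["corpus"], called_txt],
               {"k": config.prioritize_k, "primary_term": config.primary_term},
               [prio_tsv], prio_stage)

    # -- partners + second sam ----------------------------------------------
    partners_txt = run_dir / "partners.txt"
    sam2_tsv = run_dir / "sam_partners.tsv"
    if "partners" in config.stages and "interactions" in paths:
        def partners_stage():
            net = net_mod.read_interactions(paths["interactions"])
            hub = config.hub or DEFAULT_SYNTH["hub"]
            partners = net_mod.partner_expansion(net, hub)
            partners_txt.write_text("\n".join(partners) + "\n")
            matrix = _load_matrix(paths)
            sub = reduce_to_signature(matrix, partners)
            pair = config.group_pair or tuple(sorted(matrix.group_labels())[:2])
            two = sub.subset_groups(list(pair))
            res = sam_two_class(two, pair, SamParams(
                n_permutations=config.sam_permutations,
                fdr_target=config.fdr_sam, seed=config.seed))
            res.to_tsv(sam2_tsv)
        _stage(run_dir, "partners",
               [paths["interactions"], paths["matrix"], paths["groups"]],
               {"hub": config.hub, **sam_params}, [partners_txt, sam2_tsv],
               partners_stage)

    # -- survival -----------------------------------------------------------
    surv_json = run_dir / "survival_report.json"
    if "survival" in config.stages and "alterations" in paths:
        def survival_stage():
            records = surv_mod.records_from_tsv(paths["survival"])
            profile = surv_mod.AlterationProfile.from_tsv(
                paths["alterations"], patients=[r.patient for r in records])
            freqs = surv_mod.alteration_frequencies(profile)
            freqs.rename("frequency").rename_axis("gene") \
                .to_csv(run_dir / "alteration_frequencies.tsv", sep="\t",
                        float_format="%.10g")
            core = surv_mod.select_core_genes(freqs, config.alt_threshold)
            (run_dir / "core_genes.txt").write_text("\n".join(core) + "\n")
            core_r, rest_r, _ = surv_mod.stratify_patients(profile, core, records)
            km_core = surv_mod.kaplan_meier(core_r)
            km_rest = surv_mod.kaplan_meier(rest_r)
            km_core.to_tsv(run_dir / "km_core.tsv")
            km_rest.to_tsv(run_dir / "km_rest.tsv")
            chi2, p = surv_mod.logrank_test(core_r, rest_r)
            surv_json.write_text(json.dumps({
                "core_genes": core, "n_core": len(core_r), "n_rest": len(rest_r),
                "median_core": km_core.median, "median_rest": km_rest.median,
                "logrank_chi2": chi2, "logrank_p": p,
            }, indent=1))
        _stage(run_dir, "survival", [paths["alterations"], paths["survival"]],
               {"alt_threshold": config.alt_threshold}, [surv_json],
               survival_stage)

    return run_dir
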