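"""Normalized expression matrices: GEO series-matrix reading, probe collapse,
signature reduction and fold changes.

The central container is :class:`ExpressionMatrix`: genes x samples log2
values plus a sample -> group mapping.  Matrices are assumed already
normalized (RMA or equivalent); nothing here renormalizes.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyResultError,
    FormatError,
    InvalidLabelsError,
    InvalidParameterError,
    KeyNotFoundError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PlatformMap",
    "read_series_matrix",
    "write_series_matrix",
    "collapse_probes",
    "reduce_to_signature",
    "fold_change",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are gene symbols (unique), columns are sample identifiers,
        entries are finite log2-scale expression values.
    groups : dict
        Mapping sample identifier -> group label; must cover every sample.
    """

    values: pd.DataFrame
    groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise InvalidParameterError(f"duplicate gene symbol {dup!r}")
        if self.values.columns.has_duplicates:
            raise InvalidParameterError("duplicate sample identifiers")
        vals = self.values.to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise InvalidParameterError("expression values must be finite")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise InvalidLabelsError(f"samples without a group label: {missing[:5]}")

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_labels(self) -> list:
        """Distinct group labels in order of first appearance across samples."""
        seen: dict = {}
        for s in self.values.columns:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def samples_in_group(self, group) -> list:
        out = [s for s in self.values.columns if self.groups[s] == group]
        if not out:
            raise KeyNotFoundError(f"group {group!r} has no samples")
        return out

    def subset_groups(self, keep: list) -> "ExpressionMatrix":
        """Restrict to samples whose group label is in ``keep``."""
        cols = [s for s in self.values.columns if self.groups[s] in keep]
        if not cols:
            raise EmptyResultError(f"no samples in groups {keep!r}")
        return ExpressionMatrix(self.values[cols].copy(),
                                {s: self.groups[s] for s in cols})

    # -- plain-TSV round trip --------------------------------------------------
    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.insert(0, "gene", df.index)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, groups: dict) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "gene":
            raise FormatError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
        df = df.set_index("gene")
        df.index.name = None
        return cls(df, dict(groups))


@dataclass
class PlatformMap:
    """Probe identifier -> gene symbol annotation (possibly one probe to
    several symbols, several probes to one symbol)."""

    table: pd.DataFrame  # columns: probe, symbol

    def __post_init__(self) -> None:
        cols = list(self.table.columns[:2])
        t = self.table.rename(columns={cols[0]: "probe", cols[1]: "symbol"})
        t = t[["probe", "symbol"]].dropna()
        t["probe"] = t["probe"].astype(str)
        t["symbol"] = t["symbol"].astype(str).str.strip()
        t = t[t["symbol"] != ""]
        if t.duplicated().any():
            t = t.drop_duplicates()
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "PlatformMap":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if df.shape[1] < 2:
            raise FormatError(f"{path}: platform map needs >=2 columns (probe, symbol)")
        return cls(df)

    def symbols_for(self, probe: str) -> list:
        return list(self.table.loc[self.table["probe"] == str(probe), "symbol"])


# ---------------------------------------------------------------------------
# GEO series-matrix text format
# ---------------------------------------------------------------------------

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def read_series_matrix(path, group_key: str | None = None,
                       group_map: dict | None = None):
    """Parse a GEO series-matrix text file.

    Returns ``(probe_values, metadata, groups)`` where ``probe_values`` is a
    probe x sample DataFrame, ``metadata`` maps each ``!Sample_*`` key to its
    per-sample values, and ``groups`` maps sample -> group label when a label
    rule is given (``group_key`` substring matched against
    ``characteristics_ch1`` entries, raw value translated through
    ``group_map``; unmapped values are kept verbatim).
    """
    meta: dict[str, list] = {}
    table_lines: list[str] = []
    in_table = False
    begin_line = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(_TABLE_BEGIN):
                in_table = True
                begin_line = lineno
                continue
            if line.startswith(_TABLE_END):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, *vals = line.split("\t")
                vals = [v.strip('"') for v in vals]
                meta.setdefault(key.lstrip("!"), []).extend(vals)
    if begin_line is None:
        raise FormatError(f"{path}: no '{_TABLE_BEGIN}' marker found")
    if not table_lines:
        raise FormatError(f"{path}: empty expression table after line {begin_line}")
    header = table_lines[0].split("\t")
    if header[0].strip('"') != "ID_REF":
        raise FormatError(
            f"{path}: line {begin_line + 1}: table header must start with \"ID_REF\"")
    df = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t")
    df.columns = [str(c).strip('"') for c in df.columns]
    df = df.set_index("ID_REF")
    df.index = df.index.astype(str).str.strip('"')
    df.index.name = None

    groups = None
    if group_key is not None:
        samples = meta.get("Sample_geo_accession") or list(df.columns)
        char_rows = [v for k, v in meta.items()
                     if k.startswith("Sample_characteristics")]
        groups = {}
        for j, sample in enumerate(samples):
            raw_val = None
            for row in char_rows:
                if j < len(row) and row[j].lower().startswith(group_key.lower()):
                    raw_val = row[j].split(":", 1)[-1].strip()
                    break
            if raw_val is None:
                continue
            groups[sample] = (group_map or {}).get(raw_val, raw_val)
    return df, meta, groups


def write_series_matrix(values: pd.DataFrame, path,
                        characteristics: dict | None = None) -> None:
    """Emit a minimal series-matrix file that :func:`read_series_matrix`
    round-trips (used by the synthetic writers and tests)."""
    with open(path, "w") as fh:
        fh.write("!Series_title\t\"synthetic series\"\n")
        fh.write("!Sample_geo_accession\t"
                 + "\t".join(f'"{c}"' for c in values.columns) + "\n")
        if characteristics:
            for key, per_sample in characteristics.items():
                fh.write("!Sample_characteristics_ch1\t"
                         + "\t".join(f'"{key}: {per_sample[c]}"' for c in values.columns)
                         + "\n")
        fh.write(_TABLE_BEGIN + "\n")
        fh.write('"ID_REF"\t' + "\t".join(f'"{c}"' for c in values.columns) + "\n")
        for probe, row in values.iterrows():
            fh.write(f'"{probe}"\t' + "\t".join(f"{v:.10g}" for v in row) + "\n")
        fh.write(_TABLE_END + "\n")


# ---------------------------------------------------------------------------
# Probe collapse and signature reduction
# ---------------------------------------------------------------------------

def collapse_probes(probe_values: pd.DataFrame, platform: PlatformMap,
                    groups: dict, rule: str = "max_mean") -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene symbols.

    ``rule='max_mean'`` keeps, per symbol, the probe with the highest mean
    expression across samples; ``rule='mean'`` averages all probes of a
    symbol.  Probes without a symbol annotation are dropped.
    """
    if rule not in ("max_mean", "mean"):
        raise InvalidParameterError(f"unknown collapse rule {rule!r}")
    ann = platform.table[platform.table["probe"].isin(probe_values.index.astype(str))]
    if ann.empty:
        raise EmptyResultError("no probe of the matrix is annotated in the platform map")
    n_dropped = probe_values.shape[0] - probe_values.index.astype(str).isin(
        set(ann["probe"])).sum()
    expanded = probe_values.loc[ann["probe"].to_numpy()].copy()
    expanded.index = ann["symbol"].to_numpy()
    if rule == "mean":
        collapsed = expanded.groupby(level=0).mean()
    else:
        means = expanded.mean(axis=1).to_numpy()
        order = np.lexsort((-means, expanded.index.to_numpy()))
        best = expanded.iloc[order]
        collapsed = best[~best.index.duplicated(keep="first")]
        collapsed = collapsed.sort_index()
    logger.info("collapse_probes: %d probes dropped (no symbol), %d symbols kept",
                n_dropped, collapsed.shape[0])
    return ExpressionMatrix(collapsed, dict(groups))


def reduce_to_signature(matrix: ExpressionMatrix, gene_list) -> ExpressionMatrix:
    """Restrict the matrix to ``gene_list`` (order preserved); the literature
    dimensional-reduction step. Case-insensitive symbol match."""
    lookup = {g.upper(): g for g in matrix.values.index}
    kept, missed = [], []
    for g in gene_list:
        hit = lookup.get(str(g).upper())
        (kept if hit is not None else missed).append(hit if hit is not None else g)
    if missed:
        logger.warning("reduce_to_signature: %d genes absent from matrix (e.g. %s)",
                       len(missed), missed[:5])
    if not kept:
        raise EmptyResultError("signature does not intersect the matrix genes")
    return ExpressionMatrix(matrix.values.loc[kept].copy(), dict(matrix.groups))


def fold_change(matrix: ExpressionMatrix, group_a, group_b, gene) -> float:
    """Signed linear fold change of ``gene`` between two groups.

    r = 2**(mean_a - mean_b); reported +r when r >= 1, else -1/r, so a
    halving prints -2.0 rather than 0.5.
    """
    if gene not in matrix.values.index:
        raise KeyNotFoundError(f"gene {gene!r} not in matrix")
    a = matrix.samples_in_group(group_a)
    b = matrix.samples_in_group(group_b)
    row = matrix.values.loc[gene]
    r = float(2.0 ** (row[a].mean() - row[b].mean()))
    return r if r >= 1.0 else -1.0 / r
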