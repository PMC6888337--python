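"""Alteration-based survival stratification: alteration frequencies,
core-gene selection, Kaplan-Meier product-limit curves and the two-group
log-rank test.

The cohort model: a patient x gene table of genomic alteration calls
(mutation / amplification / deletion / fusion / other) joined to
progression-free survival records (time in months, event = relapse or
progression).  Patients altered in any "core" gene (alteration frequency
>= threshold, default 4%) are compared against patients altered only in
non-core genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedTestError,
)

logger = logging.getLogger(__name__)

__all__ = ["AlterationProfile", "SurvivalRecord", "KmCurve",
           "alteration_frequencies", "select_core_genes", "stratify_patients",
           "kaplan_meier", "logrank_test"]

ALTERATION_CLASSES = ("mutation", "amplification", "deletion", "fusion", "other")


@dataclass
class AlterationProfile:
    """Patient x gene binary alteration calls with per-call class labels.

    ``calls`` is a boolean DataFrame (patients x genes); ``classes`` maps
    (patient, gene) -> alteration class for altered cells only.
    """

    calls: pd.DataFrame
    classes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(bool)
        if self.calls.index.has_duplicates or self.calls.columns.has_duplicates:
            raise InvalidParameterError("duplicate patient or gene identifiers")
        for (p, g) in self.classes:
            if not self.calls.at[p, g]:
                raise InvalidParameterError(
                    f"class label on unaltered cell ({p}, {g})")

    @property
    def patients(self) -> list:
        return list(self.calls.index)

    @property
    def genes(self) -> list:
        return list(self.calls.columns)

    def altered_genes_of(self, patient) -> set:
        row = self.calls.loc[patient]
        return set(row.index[row])

    # long-form TSV: patient, gene, alteration_class (altered cells only)
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("patient\tgene\talteration_class\n")
            for p in self.calls.index:
                for g in self.calls.columns:
                    if self.calls.at[p, g]:
                        fh.write(f"{p}\t{g}\t{self.classes.get((p, g), 'other')}\n")

    @classmethod
    def from_tsv(cls, path, patients=None, genes=None) -> "AlterationProfile":
        df = pd.read_csv(path, sep="\t", dtype=str)
        pats = list(patients) if patients is not None else sorted(df["patient"].unique())
        gs = list(genes) if genes is not None else sorted(df["gene"].unique())
        calls = pd.DataFrame(False, index=pats, columns=gs)
        classes = {}
        for row in df.itertuples(index=False):
            if row.patient in calls.index and row.gene in calls.columns:
                calls.at[row.patient, row.gene] = True
                classes[(row.patient, row.gene)] = row.alteration_class
        return cls(calls, classes)


@dataclass
class SurvivalRecord:
    """One patient's follow-up: time in months, event=1 for
    relapse/progression, 0 for censoring."""

    patient: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise InvalidInputError(f"invalid time {self.time!r} for {self.patient}")
        if self.event not in (0, 1):
            raise InvalidInputError("event must be 0 or 1")


def records_to_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("patient\ttime_months\tevent\n")
        for r in records:
            fh.write(f"{r.patient}\t{r.time:.6g}\t{r.event}\n")


def records_from_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [SurvivalRecord(str(r.patient), float(r.time_months), int(r.event))
            for r in df.itertuples(index=False)]


@dataclass
class KmCurve:
    """Product-limit estimate: S(t) step function with at-risk counts."""

    times: np.ndarray            # distinct event times, ascending
    survival: np.ndarray         # S(t) just after each event time
    at_risk: np.ndarray          # n at risk just before each event time
    n_events: np.ndarray
    median: float | None         # smallest t with S(t) <= 0.5; None if never

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_tsv(self, path) -> None:
        pd.DataFrame({"time": self.times, "survival": self.survival,
                      "at_risk": self.at_risk, "events": self.n_events}) \
            .to_csv(path, sep="\t", index=False, float_format="%.10g")


def alteration_frequencies(profile: AlterationProfile) -> pd.Series:
    """Fraction of patients altered, per gene."""
    if profile.calls.shape[0] < 1:
        raise InvalidParameterError("profile has no patients")
    return profile.calls.mean(axis=0)


def select_core_genes(freqs: pd.Series, threshold: float = 0.04) -> list:
    """Genes at or above the alteration-frequency threshold,
    frequency-descending (symbol as tie-break).

    Frequencies are rounded to whole percent before the >= comparison so a
    14/353 = 3.97% gene still counts as "4%", matching how such cohorts
    round their cutoffs.
    """
    rounded = freqs.round(2)
    keep = rounded[(rounded >= threshold - 1e-12) & (freqs > 0)]
    return sorted(keep.index, key=lambda g: (-keep[g], str(g)))


def stratify_patients(profile: AlterationProfile, core_genes, records,
                      events_only: bool = True):
    """Split altered patients into core-altered vs non-core-altered cohorts.

    group_core: patients altered in >= 1 core gene.  group_rest: patients
    altered only in non-core genes.  Alteration-free patients are excluded.
    When ``events_only`` both groups are restricted to patients with a
    relapse/progression event.  Returns (core_records, rest_records,
    exclusion_report).
    """
    core = {str(g).upper() for g in core_genes}
    by_patient = {r.patient: r for r in records}
    excluded = []
    core_recs, rest_recs = [], []
    for p in profile.patients:
        altered = {str(g).upper() for g in profile.altered_genes_of(p)}
        if not altered:
            continue
        rec = by_patient.get(p)
        if rec is None:
            excluded.append({"patient": p, "reason": "no survival record"})
            continue
        if events_only and rec.event != 1:
            continue
        (core_recs if altered & core else rest_recs).append(rec)
    if excluded:
        logger.warning("stratify_patients: %d altered patients lack survival "
                       "records", len(excluded))
    return core_recs, rest_recs, pd.DataFrame(excluded, columns=["patient", "reason"])


def kaplan_meier(records) -> KmCurve:
    """Product-limit estimator with simultaneous-event tie handling."""
    if not records:
        raise InvalidInputError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if (times < 0).any():
        raise InvalidInputError("negative survival time")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events == 1])
    n = len(times)
    surv, risk, nev = [], [], []
    s = 1.0
    for t in uniq:
        at_risk = int(np.count_nonzero(times >= t))
        d = int(np.count_nonzero((times == t) & (events == 1)))
        s *= (at_risk - d) / at_risk
        surv.append(s)
        risk.append(at_risk)
        nev.append(d)
    surv = np.array(surv)
    median = None
    hit = np.nonzero(surv <= 0.5)[0]
    if hit.size:
        median = float(uniq[hit[0]])
    return KmCurve(times=uniq, survival=surv, at_risk=np.array(risk, int),
                   n_events=np.array(nev, int), median=median)


def logrank_test(records_a, records_b):
    """Two-group log-rank test: (chi_square, p_value), 1 df.

    At each distinct pooled event time the observed events in group A are
    compared to their hypergeometric expectation given the at-risk counts.
    """
    ta = np.array([r.time for r in records_a], float)
    ea = np.array([r.event for r in records_a], int)
    tb = np.array([r.time for r in records_b], float)
    eb = np.array([r.event for r in records_b], int)
    if (ea.sum() + eb.sum()) == 0:
        raise UndefinedTestError("no events in either group")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        na = int(np.count_nonzero(ta >= t))
        nb = int(np.count_nonzero(tb >= t))
        da = int(np.count_nonzero((ta == t) & (ea == 1)))
        db = int(np.count_nonzero((tb == t) & (eb == 1)))
        nt, dt = na + nb, da + db
        if nt < 2 or na == 0 or nb == 0:
            o_minus_e += da - dt * na / nt if nt else 0.0
            continue
        e = dt * na / nt
        v = dt * (na / nt) * (nb / nt) * (nt - dt) / (nt - 1)
        o_minus_e += da - e
        var += v
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
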