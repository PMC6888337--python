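"""Kaplan-Meier, log-rank, alteration frequencies and stratification."""

import numpy as np
import pandas as pd
import pytest

from litsig.errors import InvalidInputError, UndefinedTestError
from litsig.survival import (
    AlterationProfile,
    SurvivalRecord,
    alteration_frequencies,
    kaplan_meier,
    logrank_test,
    records_from_tsv,
    records_to_tsv,
    select_core_genes,
    stratify_patients,
)
from litsig.synthetic import synth_survival_alterations


def recs(spec):
    return [SurvivalRecord(f"P{i}", t, e) for i, (t, e) in enumerate(spec)]


class TestKaplanMeier:
    def test_all_events_product_limit_by_hand(self):
        km = kaplan_meier(recs([(1, 1), (2, 1), (3, 1)]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_all_censored_flat(self):
        km = kaplan_meier(recs([(1, 0), (2, 0), (3, 0)]))
        assert km.survival_at(10) == 1.0
        assert km.median is None

    def test_tie_handling(self):
        # events at t=2 twice with n=4 at risk -> S(2) = 2/4
        km = kaplan_meier(recs([(2, 1), (2, 1), (5, 0), (6, 0)]))
        assert km.survival_at(2) == pytest.approx(0.5)

    def test_equals_one_minus_ecdf_without_censoring(self, rng):
        times = rng.exponential(10, size=40)
        km = kaplan_meier(recs([(t, 1) for t in times]))
        for t in np.percentile(times, [10, 50, 90]):
            ecdf = np.mean(times <= t)
            assert km.survival_at(t) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_matches_lifelines(self, rng):
        times = rng.exponential(10, size=60)
        events = (rng.random(60) < 0.7).astype(int)
        km = kaplan_meier(recs(list(zip(times, events))))
        from lifelines import KaplanMeierFitter
        kmf = KaplanMeierFitter().fit(times, events)
        for t in np.percentile(times, [20, 50, 80]):
            assert km.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            kaplan_meier([SurvivalRecord("P", -1.0, 1)])


class TestLogrank:
    def test_identical_groups_null(self):
        a = recs([(1, 1), (2, 1), (3, 0)])
        chi2, p = logrank_test(a, a)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_hand_worked_small_fixture(self):
        # A: events at 1, 2; B: events at 3, 4.  At each event time compute
        # O-E and V by hand over the hypergeometric margins.
        a = recs([(1, 1), (2, 1)])
        b = recs([(3, 1), (4, 1)])
        o_e, v = 0.0, 0.0
        # t=1: na=2, nb=2, d=1 -> E=0.5, V=1*(2/4)*(2/4)*(3)/(3)=0.25
        o_e += 1 - 0.5; v += (2 / 4) * (2 / 4) * (4 - 1) / (4 - 1)
        # t=2: na=1, nb=2, d=1 -> E=1/3, V=(1/3)*(2/3)*(2/2)=2/9
        o_e += 1 - 1 / 3; v += (1 / 3) * (2 / 3)
        # t=3: na=0, nb=2 -> group A exhausted, no variance contribution
        # t=4: na=0, nb=1 -> likewise
        from scipy import stats
        chi2_hand = o_e ** 2 / v
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx(chi2_hand, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(chi2_hand, 1), rel=1e-10)

    def test_symmetry(self, rng):
        a = recs([(t, 1) for t in rng.exponential(5, 20)])
        b = recs([(t, 1) for t in rng.exponential(9, 20)])
        assert logrank_test(a, b) == pytest.approx(logrank_test(b, a))

    def test_matches_lifelines(self, rng):
        a = [(t, int(e)) for t, e in zip(rng.exponential(5, 30),
                                         rng.random(30) < 0.8)]
        b = [(t, int(e)) for t, e in zip(rng.exponential(12, 25),
                                         rng.random(25) < 0.8)]
        chi2, p = logrank_test(recs(a), recs(b))
        from lifelines.statistics import logrank_test as ll_logrank
        res = ll_logrank([x[0] for x in a], [x[0] for x in b],
                         [x[1] for x in a], [x[1] for x in b])
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-8)
        assert p == pytest.approx(res.p_value, rel=1e-8)

    def test_no_events_undefined(self):
        a = recs([(1, 0), (2, 0)])
        with pytest.raises(UndefinedTestError):
            logrank_test(a, a)


class TestAlterations:
    def make_profile(self):
        calls = pd.DataFrame(
            [[True, False, False],
             [True, True, False],
             [False, False, False],
             [False, True, False]],
            index=[f"P{i}" for i in range(4)], columns=["A", "B", "C"])
        return AlterationProfile(calls, {("P0", "A"): "mutation",
                                         ("P1", "A"): "deletion",
                                         ("P1", "B"): "amplification",
                                         ("P3", "B"): "mutation"})

    def test_frequencies_match_column_means(self, rng):
        calls = pd.DataFrame(rng.random((20, 6)) < 0.3,
                             index=[f"P{i}" for i in range(20)],
                             columns=[f"g{j}" for j in range(6)])
        prof = AlterationProfile(calls)
        np.testing.assert_allclose(alteration_frequencies(prof).to_numpy(),
                                   calls.to_numpy().mean(axis=0))

    def test_no_alterations_zero(self):
        prof = AlterationProfile(pd.DataFrame(False, index=["P1", "P2"],
                                              columns=["A"]))
        assert alteration_frequencies(prof).tolist() == [0.0]

    def test_cohort_fraction_example(self):
        # 14 altered of 353 patients ~ 3.97%, counted as the 4% cutoff
        calls = pd.DataFrame(False, index=[f"P{i}" for i in range(353)],
                             columns=["G"])
        calls.iloc[:14] = True
        freq = alteration_frequencies(AlterationProfile(calls))
        assert freq["G"] == pytest.approx(14 / 353)
        assert select_core_genes(freq, 0.04) == ["G"]

    def test_select_core_thresholds(self):
        freqs = pd.Series({"A": 0.10, "B": 0.04, "C": 0.01, "D": 0.0})
        assert select_core_genes(freqs, 0.04) == ["A", "B"]
        assert select_core_genes(freqs, 0.0) == ["A", "B", "C"]
        assert select_core_genes(freqs, 0.99) == []

    def test_round_trip_tsv(self, tmp_path):
        prof = self.make_profile()
        path = tmp_path / "alt.tsv"
        prof.to_tsv(path)
        back = AlterationProfile.from_tsv(path, patients=prof.patients,
                                          genes=prof.genes)
        pd.testing.assert_frame_equal(back.calls, prof.calls)
        assert back.classes == prof.classes


class TestStratification:
    def test_partition_and_core_priority(self):
        prof = TestAlterations().make_profile()
        records = recs([(5, 1), (6, 1), (7, 1), (8, 1)])
        core_r, rest_r, _ = stratify_patients(prof, ["A"], records,
                                              events_only=False)
        core_ids = {r.patient for r in core_r}
        rest_ids = {r.patient for r in rest_r}
        assert core_ids == {"P0", "P1"}      # P1 altered in core and non-core
        assert rest_ids == {"P3"}            # P2 alteration-free: excluded
        assert core_ids.isdisjoint(rest_ids)

    def test_no_core_genes(self):
        prof = TestAlterations().make_profile()
        records = recs([(5, 1)] * 4)
        core_r, rest_r, _ = stratify_patients(prof, [], records,
                                              events_only=False)
        assert core_r == []
        assert {r.patient for r in rest_r} == {"P0", "P1", "P3"}

    def test_events_only_filter(self):
        prof = TestAlterations().make_profile()
        records = recs([(5, 1), (6, 0), (7, 1), (8, 0)])
        core_r, rest_r, _ = stratify_patients(prof, ["A"], records,
                                              events_only=True)
        assert {r.patient for r in core_r} == {"P0"}
        assert rest_r == []

    def test_unjoinable_reported_not_fatal(self):
        prof = TestAlterations().make_profile()
        records = recs([(5, 1)])  # only P0
        _, _, report = stratify_patients(prof, ["A"], records,
                                         events_only=False)
        assert set(report["patient"]) == {"P1", "P3"}

    def test_synthetic_exact_recovery(self):
        prof, records, truth = synth_survival_alterations(
            200, ["A", "B", "C", "D"], [0.2, 0.2, 0.05, 0.05], {"A", "B"},
            3.0, 0.02, 0.0, seed=5)
        freqs = alteration_frequencies(prof)
        core = select_core_genes(freqs, 0.1)
        assert set(core) == truth.altered_core_genes
        core_r, rest_r, _ = stratify_patients(prof, core, records)
        core_ids = {r.patient for r in core_r}
        oracle_core = {p for p in prof.patients
                       if prof.altered_genes_of(p) & {"A", "B"}}
        assert core_ids == oracle_core


class TestRecordsIO:
    def test_round_trip(self, tmp_path):
        rs = recs([(5.5, 1), (2.25, 0)])
        path = tmp_path / "surv.tsv"
        records_to_tsv(rs, path)
        back = records_from_tsv(path)
        assert [(r.patient, r.time, r.event) for r in back] == \
            [(r.patient, r.time, r.event) for r in rs]
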