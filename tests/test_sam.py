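"""SAM: statistic, fudge factor, permutation FDR, oracle equality."""

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from litsig.errors import DegenerateDataError, InvalidLabelsError
from litsig.expression import ExpressionMatrix
from litsig.sam import SAM, SamParams, estimate_s0, sam_d_statistics, sam_two_class
from litsig.synthetic import synth_expression


def matrix_from_arrays(x, n1, n2):
    genes = [f"G{i}" for i in range(x.shape[0])]
    samples = [f"S{j}" for j in range(n1 + n2)]
    groups = {s: ("g1" if j < n1 else "g2") for j, s in enumerate(samples)}
    return ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), groups)


class TestDStatistic:
    def test_hand_computed_example(self):
        # group1=(1,2,3), group2=(3,4,5), s0=0:
        # r = 2, s = sqrt[(1/3+1/3)/4 * (2+2)] = sqrt(2/3), d = 2/sqrt(2/3)
        m = matrix_from_arrays(np.array([[1.0, 2, 3, 3, 4, 5]]), 3, 3)
        r, s, d = sam_d_statistics(m, ("g1", "g2"), s0=0.0)
        assert r[0] == pytest.approx(2.0)
        assert s[0] == pytest.approx(np.sqrt(2.0 / 3.0))
        assert d[0] == pytest.approx(2.0 / np.sqrt(2.0 / 3.0))

    def test_identical_groups_zero(self):
        m = matrix_from_arrays(np.array([[1.0, 2, 3, 1, 2, 3]]), 3, 3)
        _, _, d = sam_d_statistics(m, ("g1", "g2"), s0=0.0)
        assert d[0] == pytest.approx(0.0)

    def test_s0_shrinks_d_monotonically(self):
        m = matrix_from_arrays(np.array([[1.0, 2, 3, 3, 4, 5]]), 3, 3)
        ds = [abs(sam_d_statistics(m, ("g1", "g2"), s0=s0)[2][0])
              for s0 in (0.0, 1.0, 10.0, 100.0)]
        assert all(a > b for a, b in zip(ds, ds[1:]))
        assert ds[-1] < 0.05

    def test_antisymmetric_under_group_swap(self, rng):
        x = rng.normal(size=(20, 10))
        m = matrix_from_arrays(x, 5, 5)
        _, _, d12 = sam_d_statistics(m, ("g1", "g2"), s0=0.1)
        _, _, d21 = sam_d_statistics(m, ("g2", "g1"), s0=0.1)
        np.testing.assert_allclose(d12, -d21, rtol=1e-12)

    def test_three_groups_rejected(self, rng):
        x = rng.normal(size=(5, 6))
        genes = [f"G{i}" for i in range(5)]
        samples = [f"S{j}" for j in range(6)]
        groups = dict(zip(samples, ["a", "a", "b", "b", "c", "c"]))
        m = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), groups)
        with pytest.raises(InvalidLabelsError):
            sam_d_statistics(m, None, 0.0)


class TestEstimateS0:
    def test_single_candidate_returned(self, rng):
        r = rng.normal(size=200)
        s = np.abs(rng.normal(1, 0.1, size=200))
        assert estimate_s0(r, s, percentiles=(50,)) == pytest.approx(
            np.percentile(s, 50))

    def test_homoscedastic_small_s0(self):
        # spread of d flat in s exactly at s0=0 (r proportional to s);
        # any positive fudge factor re-introduces an s-trend
        vals = []
        for seed in range(5):
            g = np.random.default_rng(seed)
            s = g.uniform(0.2, 2.0, size=2000)
            r = g.normal(0, 1.0, size=2000) * s
            vals.append(estimate_s0(r, s))
        assert np.median(vals) <= np.percentile(s, 10)

    def test_heteroscedastic_positive_s0(self):
        # noise rising steeply with s: small-s genes get inflated d unless
        # a positive fudge factor is added
        g = np.random.default_rng(7)
        s = np.linspace(0.05, 2.0, 3000)
        r = g.normal(0, 1, size=3000) * (0.2 + s ** 2)
        assert estimate_s0(r, s) > 0.0

    def test_all_zero_scales_degenerate(self):
        with pytest.raises(DegenerateDataError):
            estimate_s0(np.zeros(10), np.zeros(10))


def oracle_sam_qvalues(x, n1, n2, s0, n_delta=200, fdr_target=0.05):
    """Loop-based exhaustive-permutation SAM q-values (independent of the
    vectorized implementation)."""
    m = x.shape[0]
    n = n1 + n2

    def rs(cols1, cols2):
        out = []
        for i in range(m):
            a = [x[i, j] for j in cols1]
            b = [x[i, j] for j in cols2]
            ma, mb = sum(a) / n1, sum(b) / n2
            ss = sum((v - ma) ** 2 for v in a) + sum((v - mb) ** 2 for v in b)
            s = ((1 / n1 + 1 / n2) / (n - 2) * ss) ** 0.5
            out.append((mb - ma) / (s + s0))
        return out

    observed = rs(range(n1), range(n1, n)); d_sorted = sorted(observed)
    perms = []
    for c in combinations(range(n), n1):
        rest = [j for j in range(n) if j not in c]
        perms.append(sorted(rs(c, rest)))
    dbar = [sum(p[i] for p in perms) / len(perms) for i in range(m)]
    allperm = sorted(v for p in perms for v in p)
    q25 = np.percentile(allperm, 25)
    q75 = np.percentile(allperm, 75)
    pi0 = min(1.0, sum(1 for v in observed if q25 <= v <= q75) / (0.5 * m))

    dmax = max(abs(a - b) for a, b in zip(d_sorted, dbar))
    deltas = np.linspace(0, dmax, n_delta)
    fdrs, cutups, cutlows = [], [], []
    for delta in deltas:
        ups = [i for i in range(m)
               if d_sorted[i] - dbar[i] >= delta and d_sorted[i] >= 0]
        los = [i for i in range(m)
               if dbar[i] - d_sorted[i] >= delta and d_sorted[i] <= 0]
        cutup = d_sorted[ups[0]] if ups else float("inf")
        cutlow = d_sorted[los[-1]] if los else float("-inf")
        called = sum(1 for v in observed if v >= cutup or v <= cutlow)
        false = [sum(1 for v in p if v >= cutup or v <= cutlow) for p in perms]
        fdrs.append(min(1.0, pi0 * float(np.median(false)) / max(1, called)))
        cutups.append(cutup)
        cutlows.append(cutlow)
    for i in range(1, n_delta):
        fdrs[i] = min(fdrs[i], fdrs[i - 1])
    qvals = []
    for v in observed:
        ks = [k for k in range(n_delta) if v >= cutups[k] or v <= cutlows[k]]
        qvals.append(fdrs[ks[-1]] if ks else 1.0)
    return np.array(qvals)


class TestTwoClass:
    def test_exhaustive_oracle_qvalues(self):
        """10 genes x 6 samples: all C(6,3)=20 label arrangements are
        enumerable; q-values must match a loop-based oracle exactly."""
        g = np.random.default_rng(11)
        x = g.normal(7, 1, size=(10, 6))
        x[:3, 3:] += 2.5
        m = matrix_from_arrays(x, 3, 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = SAM(m, ("g1", "g2")).fit(SamParams(n_permutations=50, seed=0))
        assert res.exact_permutations
        oracle_q = oracle_sam_qvalues(x, 3, 3, res.s0)
        np.testing.assert_allclose(res.table["q"].to_numpy(), oracle_q,
                                   rtol=1e-10, atol=1e-12)

    def test_seed_reproducibility(self):
        m, _ = synth_expression(150, [8, 8], 15, 1.0, 0.5, 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = sam_two_class(m, params=SamParams(n_permutations=80, seed=5))
            r2 = sam_two_class(m, params=SamParams(n_permutations=80, seed=5))
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.delta == r2.delta and r1.pi0 == r2.pi0

    def test_expected_order_stats_invariant_to_gene_order(self):
        m, _ = synth_expression(120, [6, 6], 10, 1.0, 0.5, 9)
        shuffled = ExpressionMatrix(m.values.sample(frac=1, random_state=1),
                                    m.groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = sam_two_class(m, params=SamParams(n_permutations=60, seed=2))
            r2 = sam_two_class(shuffled, params=SamParams(n_permutations=60, seed=2))
        np.testing.assert_allclose(r1.expected_order_stats,
                                   r2.expected_order_stats, rtol=1e-12)

    def test_fdr_grid_non_increasing(self):
        m, _ = synth_expression(200, [8, 8], 20, 1.0, 0.5, 4)
        res = sam_two_class(m, params=SamParams(n_permutations=60, seed=1))
        assert np.all(np.diff(res.fdr_grid) <= 1e-15)

    def test_calls_unchanged_under_group_swap(self):
        m, _ = synth_expression(200, [8, 8], 20, 1.2, 0.5, 8)
        r12 = sam_two_class(m, ("grpA", "grpB"),
                            SamParams(n_permutations=100, seed=3))
        r21 = sam_two_class(m, ("grpB", "grpA"),
                            SamParams(n_permutations=100, seed=3))
        assert set(r12.called_genes) == set(r21.called_genes)

    def test_fold_change_column_signed(self):
        x = np.tile([5.0, 5, 5, 6, 6, 6], (2, 1))
        x[1] = [6.0, 6, 6, 5, 5, 5]
        x += np.random.default_rng(0).normal(0, 1e-6, x.shape)
        m = matrix_from_arrays(x, 3, 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = SAM(m, ("g1", "g2")).fit(SamParams(n_permutations=50, seed=0))
        assert res.table.loc["G0", "fold_change"] == pytest.approx(2.0, abs=1e-4)
        assert res.table.loc["G1", "fold_change"] == pytest.approx(-2.0, abs=1e-4)

    def test_summary_mentions_key_quantities(self):
        m, _ = synth_expression(120, [6, 6], 10, 1.0, 0.5, 9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sam_two_class(m, params=SamParams(n_permutations=60, seed=2))
        text = res.summary()
        assert "s0" in text and "delta" in text and "genes called" in text
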