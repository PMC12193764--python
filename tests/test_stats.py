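from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import rankdata

from natval.core import ValidationError
from natval.stats import (DistanceMatrix, anosim, bray_curtis_matrix,
                          kendall_tau_b, pairwise_anosim, shapiro_wilk)

from conftest import community_from_matrix


def naive_bray_curtis(x, y):
    return sum(abs(a - b) for a, b in zip(x, y)) / sum(a + b for a, b in zip(x, y))


def naive_anosim_r(d, labels):
    """Rank-based R recomputed with explicit loops."""
    n = len(labels)
    iu = list(zip(*np.triu_indices(n, 1)))
    ranks = rankdata([d[i, j] for i, j in iu])
    within = [ranks[k] for k, (i, j) in enumerate(iu) if labels[i] == labels[j]]
    between = [ranks[k] for k, (i, j) in enumerate(iu) if labels[i] != labels[j]]
    return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4)


def random_distance_matrix(n, rng):
    d = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    d[iu] = rng.random(len(iu[0]))
    return d + d.T


class TestBrayCurtis:
    def test_identical_and_disjoint_rows(self):
        comm = community_from_matrix([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 1]])
        dm = bray_curtis_matrix(comm)
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == 1.0

    def test_hand_worked_pair(self):
        comm = community_from_matrix([[1, 2, 0], [0, 2, 4]])
        dm = bray_curtis_matrix(comm)
        assert dm.values[0, 1] == pytest.approx(5 / 9)

    def test_all_zero_row_is_domain_error(self):
        comm = community_from_matrix([[1, 2], [0, 0]])
        with pytest.raises(ValidationError, match="T1"):
            bray_curtis_matrix(comm)

    def test_ad_currency_divides_by_active_days(self):
        comm = community_from_matrix([[10, 0], [0, 30]],
                                     active_days=[10.0, 30.0])
        dm_ad = bray_curtis_matrix(comm, "ad")
        dm_ct = bray_curtis_matrix(comm, "counts")
        assert dm_ad.values[0, 1] == 1.0 == dm_ct.values[0, 1]
        assert comm.ad.iloc[0, 0] == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, st.tuples(st.integers(2, 6), st.integers(1, 5)),
                      elements=st.floats(0, 100, allow_nan=False)))
    def test_symmetry_range_and_oracle(self, X):
        X[:, 0] += 1.0  # no empty rows
        dm = bray_curtis_matrix(community_from_matrix(X))
        v = dm.values
        assert np.allclose(v, v.T)
        assert np.all((v >= 0) & (v <= 1 + 1e-12))
        assert v[0, 1] == pytest.approx(naive_bray_curtis(X[0], X[1]))


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        comm = community_from_matrix([[9, 1, 0, 0], [8, 2, 0, 0],
                                      [0, 0, 7, 3], [0, 0, 6, 4]])
        res = anosim(bray_curtis_matrix(comm), ["a", "a", "b", "b"],
                     n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_r_and_p_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        d = random_distance_matrix(6, rng)
        labels = np.array(["g1"] * 3 + ["g2"] * 3)
        dm = DistanceMatrix(labels=[f"T{i}" for i in range(6)], values=d)
        res = anosim(dm, labels, n_perm=9999, seed=1)
        assert res.R == pytest.approx(naive_anosim_r(d, labels))
        all_r = [naive_anosim_r(d, p) for p in set(permutations(labels))]
        p_exact = np.mean([r >= res.R - 1e-12 for r in all_r])
        # sampled +1/+1 estimator converges on the exhaustive proportion
        assert res.p == pytest.approx(p_exact, abs=0.03)
        assert res.p >= 1 / (9999 + 1)

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import anosim as sk_anosim
        rng = np.random.default_rng(3)
        X = rng.integers(0, 20, (12, 6)).astype(float)
        X[:, 0] += 1
        dm = bray_curtis_matrix(community_from_matrix(X))
        labels = np.repeat(["a", "b", "c"], 4)
        mine = anosim(dm, labels, n_perm=999, seed=0)
        theirs = sk_anosim(SkDM(dm.values, ids=dm.labels), grouping=list(labels),
                           permutations=999)
        assert mine.R == pytest.approx(theirs["test statistic"])
        assert mine.p == pytest.approx(theirs["p-value"], abs=0.03)

    def test_invariant_under_monotone_distance_transform(self):
        rng = np.random.default_rng(11)
        d = random_distance_matrix(8, rng)
        labels = np.repeat(["a", "b"], 4)
        ids = [f"T{i}" for i in range(8)]
        res1 = anosim(DistanceMatrix(labels=ids, values=d), labels,
                      n_perm=499, seed=5)
        res2 = anosim(DistanceMatrix(labels=ids, values=np.sqrt(d)), labels,
                      n_perm=499, seed=5)
        assert res1.R == pytest.approx(res2.R)
        assert res1.p == res2.p

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(2)
        d = random_distance_matrix(10, rng)
        labels = np.repeat(["a", "b"], 5)
        ids = [f"T{i}" for i in range(10)]
        a = anosim(DistanceMatrix(labels=ids, values=d), labels, 999, seed=7)
        b = anosim(DistanceMatrix(labels=ids, values=d), labels, 999, seed=7)
        assert (a.R, a.p) == (b.R, b.p)

    def test_singleton_group_policy(self):
        rng = np.random.default_rng(4)
        d = random_distance_matrix(5, rng)
        labels = np.array(["a", "a", "b", "b", "c"])
        dm = DistanceMatrix(labels=[f"T{i}" for i in range(5)], values=d)
        with pytest.raises(ValidationError, match="c"):
            anosim(dm, labels, n_perm=9, seed=0, strict=True)
        res = anosim(dm, labels, n_perm=9, seed=0, strict=False)
        assert res.n_sites == 4 and res.groups == ["a", "b"]


class TestPairwiseAnosim:
    def test_duplicated_group_is_indistinct(self):
        X = np.array([[5, 1, 0], [4, 2, 0], [5, 2, 1], [5, 1, 0],
                      [4, 2, 0], [5, 2, 1]], dtype=float)
        dm = bray_curtis_matrix(community_from_matrix(X))
        out = pairwise_anosim(dm, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        row = out.iloc[0]
        assert row["R"] <= 0.0 and row["p_adjusted"] > 0.5

    def test_bonferroni_arithmetic_over_all_pairs(self):
        rng = np.random.default_rng(9)
        X = rng.integers(1, 30, (16, 8)).astype(float)
        dm = bray_curtis_matrix(community_from_matrix(X))
        labels = np.repeat([f"g{i}" for i in range(4)], 4)
        out = pairwise_anosim(dm, labels, n_perm=99, seed=3)
        assert len(out) == 6
        assert np.allclose(out["p_adjusted"],
                           np.minimum(1.0, out["p_raw"] * 6))

    def test_bad_pair_is_flagged_not_fatal(self):
        rng = np.random.default_rng(9)
        d = random_distance_matrix(6, rng)
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        dm = DistanceMatrix(labels=[f"T{i}" for i in range(6)], values=d)
        out = pairwise_anosim(dm, labels, n_perm=9, seed=0)
        assert out["error"].eq("").all()
        assert len(out) == 3


class TestKendall:
    def test_strictly_monotone_no_ties_is_one(self):
        res = kendall_tau_b([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res.tau_b == pytest.approx(1.0)

    def test_tied_case_matches_pair_count_oracle(self):
        x = np.array([1, 2, 2, 3, 3, 3, 4, 5, 5, 6], dtype=float)
        rng = np.random.default_rng(1)
        y = np.round(x + rng.normal(0, 1.5, len(x)))
        C = D = 0
        for i in range(len(x)):
            for j in range(i + 1, len(x)):
                s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
                C += s > 0
                D += s < 0
        n0 = len(x) * (len(x) - 1) / 2
        n1 = sum(k * (k - 1) / 2 for k in pd.Series(x).value_counts())
        n2 = sum(k * (k - 1) / 2 for k in pd.Series(y).value_counts())
        tau_oracle = (C - D) / np.sqrt((n0 - n1) * (n0 - n2))
        res = kendall_tau_b(x, y)
        assert res.tau_b == pytest.approx(tau_oracle)
        assert res.n == len(x)

    def test_all_tied_vector_is_domain_error(self):
        with pytest.raises(ValidationError):
            kendall_tau_b([1, 1, 1, 1], [1, 2, 3, 4])


class TestShapiroWilk:
    def test_near_normal_large_sample_w_close_to_one(self):
        x = np.random.default_rng(0).normal(size=2000)
        res = shapiro_wilk(x)
        assert res.W > 0.995

    def test_five_point_case_against_published_coefficients(self):
        # W from the original tabulated order-statistic coefficients for n=5
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        b = 0.6646 * (x[4] - x[0]) + 0.2413 * (x[3] - x[1])
        w_table = b**2 / ((x - x.mean()) ** 2).sum()
        assert shapiro_wilk(x).W == pytest.approx(w_table, abs=5e-3)

    def test_constant_sample_is_domain_error(self):
        with pytest.raises(ValidationError):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])
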