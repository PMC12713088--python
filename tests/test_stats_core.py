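"""Hypergeometric tails, representation factor, BH-FDR, correlation, rank tests."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromtargets.stats_core import (
    OverlapResult,
    bh_fdr,
    hypergeom_tail,
    overlap_result,
    pearson_corr_matrix,
    rank_test,
    representation_factor,
)


def exact_hypergeom_pmf(N: int, K: int, n: int) -> dict[int, Fraction]:
    """Rational pmf by direct counting of draws."""
    denom = math.comb(N, n)
    lo, hi = max(0, K + n - N), min(K, n)
    return {
        k: Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
        for k in range(lo, hi + 1)
    }


class TestHypergeomTail:
    def test_whole_support_upper_tail_is_one(self):
        assert hypergeom_tail(0, 5, 4, 10, "upper") == 1.0

    def test_small_enumeration_example(self):
        # drawing 4 from 10 with 5 marked; all-4-marked has 5 of C(10,4) draws
        assert hypergeom_tail(4, 5, 4, 10, "upper") == pytest.approx(5 / 210, rel=1e-12)

    def test_genome_scale_two_tailed_value(self):
        # overlap of 1396 between sets of 7982 and 5259 in a 32548-gene
        # universe: the minimum-likelihood two-tailed p prints as 2.21E-4
        p = hypergeom_tail(1396, 7982, 5259, 32548, "two", "min_likelihood")
        assert p == pytest.approx(2.21e-4, rel=5e-3)
        p_double = hypergeom_tail(1396, 7982, 5259, 32548, "two", "double_one_tail")
        assert 0.5 < p_double / p < 2.0

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(5, 4, 4, 10, "upper")

    def test_tails_match_rational_enumeration_exhaustively(self):
        # exact equality against a rational-arithmetic oracle on small universes
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    pmf = exact_hypergeom_pmf(N, K, n)
                    for k in pmf:
                        upper = float(sum(v for j, v in pmf.items() if j >= k))
                        lower = float(sum(v for j, v in pmf.items() if j <= k))
                        assert hypergeom_tail(k, K, n, N, "upper") == pytest.approx(upper, rel=1e-10)
                        assert hypergeom_tail(k, K, n, N, "lower") == pytest.approx(lower, rel=1e-10)

    def test_minlike_matches_enumeration_on_random_instances(self, rng):
        for _ in range(200):
            N = int(rng.integers(13, 26))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            pmf = exact_hypergeom_pmf(N, K, n)
            k = int(rng.choice(list(pmf)))
            expect = float(sum(v for v in pmf.values() if v <= pmf[k]))
            assert hypergeom_tail(k, K, n, N, "two", "min_likelihood") == pytest.approx(
                min(1.0, expect), rel=1e-9
            )

    def test_pmf_sums_to_one(self):
        from scipy.stats import hypergeom

        for N in (17, 60, 200):
            K, n = N // 3, N // 2
            supp = np.arange(max(0, K + n - N), min(K, n) + 1)
            assert hypergeom.pmf(supp, N, K, n).sum() == pytest.approx(1.0, abs=1e-9)


class TestRepresentationFactor:
    def test_expected_overlap_gives_one(self):
        assert representation_factor(6, 20, 30, 100) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "k,K,n,N,printed",
        [(3537, 7982, 8096, 32548, 1.8), (1396, 7982, 5259, 32548, 1.1)],
    )
    def test_genome_scale_rf_values(self, k, K, n, N, printed):
        assert round(representation_factor(k, K, n, N), 1) == printed

    def test_overlap_result_invariants(self):
        r = overlap_result(30, 50, 40, 100)
        assert r.expected == pytest.approx(20.0)
        assert r.rf == pytest.approx(1.5)
        assert 0 < r.p_one <= 1
        with pytest.raises(ValueError):
            OverlapResult(100, 50, 40, 45, 20.0, 2.25, 0.1, 0.2, "min_likelihood")


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_by_hand(self):
        q = bh_fdr([0.01, 0.04, 0.03, 0.05])
        assert q == pytest.approx([0.04, 0.05, 0.05, 0.05])

    def test_ties_all_equal(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_rejects_nan_and_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, float("nan")])
        with pytest.raises(ValueError):
            bh_fdr([1.5])

    def test_threshold_matches_textbook_step_up(self, rng):
        # rejection set at q <= alpha equals the classic step-up rule
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            alpha = float(rng.uniform(0.01, 0.2))
            q = bh_fdr(p)
            order = np.argsort(p)
            k_star = 0
            for i, idx in enumerate(order, 1):
                if p[idx] <= alpha * i / m:
                    k_star = i
            expected = set(order[:k_star].tolist())
            assert set(np.flatnonzero(q <= alpha).tolist()) == expected


class TestPearson:
    def test_self_correlation(self):
        import pandas as pd

        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 1, 4, 3]})
        c = pearson_corr_matrix(df, transform="identity")
        assert c.loc["a", "a"] == pytest.approx(1.0)
        assert np.allclose(c.values, c.values.T)

    def test_anticorrelation_and_hand_value(self):
        import pandas as pd

        df = pd.DataFrame({"x": [1.0, 2, 3], "negx": [-1.0, -2, -3], "y": [1.0, 2, 4]})
        c = pearson_corr_matrix(df, transform="identity")
        assert c.loc["x", "negx"] == pytest.approx(-1.0)
        assert c.loc["x", "y"] == pytest.approx(0.9820, abs=1e-4)

    def test_zero_variance_sample_named(self):
        import pandas as pd

        df = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [2.0, 2, 2]})
        with pytest.raises(ValueError, match="flat"):
            pearson_corr_matrix(df, transform="identity")


def _mwu_brute_force(a, b, alternative="two-sided"):
    """Independent label-permutation oracle for the exact MWU p."""
    from scipy.stats import rankdata

    pooled = list(a) + list(b)
    ranks = rankdata(pooled)
    na = len(a)
    u_obs = sum(ranks[:na]) - na * (na + 1) / 2
    us = []
    for perm in set(itertools.permutations(range(len(pooled)))):
        us.append(sum(ranks[i] for i in perm[:na]) - na * (na + 1) / 2)
    us = np.array(us)
    pg, pl = np.mean(us >= u_obs - 1e-9), np.mean(us <= u_obs + 1e-9)
    if alternative == "greater":
        return pg
    if alternative == "less":
        return pl
    return min(1.0, 2 * min(pg, pl))


class TestRankTest:
    def test_two_vs_two_exact(self):
        u, p = rank_test([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_label_swap_symmetry(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=4)
        _, p1 = rank_test(a, b)
        _, p2 = rank_test(b, a)
        assert p1 == pytest.approx(p2)

    def test_exact_matches_permutation_oracle_with_ties(self, rng):
        for _ in range(25):
            na, nb = int(rng.integers(1, 5)), int(rng.integers(1, 4))
            vals = rng.integers(0, 4, size=na + nb).astype(float)  # many ties
            a, b = vals[:na], vals[na:]
            _, p = rank_test(a, b)
            assert p == pytest.approx(_mwu_brute_force(a, b), abs=1e-12)

    def test_large_sample_uses_normal_approximation(self, rng):
        from scipy.stats import mannwhitneyu

        a, b = rng.normal(size=30), rng.normal(0.5, size=25)
        u, p = rank_test(a, b)
        ref = mannwhitneyu(a, b, method="asymptotic")
        assert (u, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))

    def test_paired_identical_vectors(self):
        assert rank_test([1, 2, 3], [1, 2, 3], mode="paired_signed_rank") == (0.0, 1.0)

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            rank_test([1, 2], [1], mode="paired_signed_rank")

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=6))
    def test_paired_signed_rank_agrees_with_scipy(self, diffs):
        from scipy.stats import wilcoxon

        a = np.array(diffs)
        b = np.zeros_like(a)
        if np.all(a == 0):
            assert rank_test(a, b, mode="paired_signed_rank")[1] == 1.0
        else:
            ref = wilcoxon(a, b, zero_method="wilcox")
            _, p = rank_test(a, b, mode="paired_signed_rank")
            assert p == pytest.approx(ref.pvalue)
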