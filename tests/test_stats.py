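"""Statistical primitives against hand values and brute-force oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cgimeth.stats import (
    chi_square_2x2,
    domain_distribution,
    group_domain_fractions,
    hypergeometric_enrichment,
    overlap_counts,
    percent_input,
    rank_sum_test,
    spearman_matrix,
    tau_index,
)
from cgimeth.track_io import GenomicInterval


class TestTau:
    def test_one_hot_expression_is_maximally_specific(self):
        assert tau_index([0, 0, 0, 7], log_transform=False) == pytest.approx(1.0)
        assert tau_index([0, 0, 0, 7], log_transform=True) == pytest.approx(1.0)

    def test_uniform_expression_is_zero(self):
        assert tau_index([3.0, 3.0, 3.0], log_transform=False) == pytest.approx(0.0)

    def test_hand_evaluated_example(self):
        # x_hat = (1, .25, .25) -> (0 + .75 + .75) / 2
        assert tau_index([8, 2, 2], log_transform=False) == pytest.approx(0.75)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            tau_index([0.0, 0.0])
        with pytest.raises(ValueError):
            tau_index([5.0])
        with pytest.raises(ValueError):
            tau_index([1.0, -1.0])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=12),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_bounded_and_scale_invariant(self, x, c):
        if max(x) <= 0:
            return
        tau = tau_index(x, log_transform=False)
        assert 0.0 <= tau <= 1.0 + 1e-12
        scaled = tau_index([c * v for v in x], log_transform=False)
        assert scaled == pytest.approx(tau, abs=1e-9)


def _midrank_pearson(a, b):
    """Independent oracle: Pearson correlation of average ranks."""
    ra = sps.rankdata(a, method="average")
    rb = sps.rankdata(b, method="average")
    return np.corrcoef(ra, rb)[0, 1]


class TestSpearman:
    def test_monotone_vectors(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [10, 20, 30, 40], "z": [4, 3, 2, 1]})
        m = spearman_matrix(df)
        assert m.loc["x", "y"] == pytest.approx(1.0)
        assert m.loc["x", "z"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m.values, m.values.T, equal_nan=True)

    def test_hand_ranked_tied_example(self):
        # b ranks (2.5, 2.5, 4, 1) -> rho = -1.5 / sqrt(5 * 4.5)
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [2, 2, 3, 1]})
        assert spearman_matrix(df).loc["a", "b"] == pytest.approx(-0.316, abs=5e-4)

    def test_matches_midrank_pearson_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            a = rng.integers(0, 5, size=n).astype(float)  # ties likely
            b = rng.integers(0, 5, size=n).astype(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            df = pd.DataFrame({"a": a, "b": b})
            assert spearman_matrix(df).loc["a", "b"] == pytest.approx(
                _midrank_pearson(a, b), abs=1e-12
            )

    def test_pairwise_complete_and_sparse_cell_missing(self):
        df = pd.DataFrame(
            {"a": [1, 2, 3, 4, 5], "b": [np.nan, np.nan, np.nan, 1, 2]}
        )
        with pytest.warns(UserWarning, match="complete pairs"):
            m = spearman_matrix(df)
        assert np.isnan(m.loc["a", "b"])


class TestChiSquare:
    def test_balanced_table_has_zero_statistic(self):
        stat, p, props = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert props == {"row1": 0.5, "row2": 0.5}

    def test_hand_computed_statistic(self):
        # 200 * (30*90 - 70*10)^2 / (100 * 100 * 40 * 160)
        stat, _, _ = chi_square_2x2([[30, 70], [10, 90]])
        assert stat == pytest.approx(12.5)

    def test_zero_marginal_is_error(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            t = rng.integers(1, 100, size=(2, 2))
            stat, p, _ = chi_square_2x2(t)
            ref = sps.chi2_contingency(t, correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-12, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12, rel=1e-9)


def _enumerate_rank_sum_p(a, b):
    """Independent oracle: doubled tail of the permutation rank-sum."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled, method="average")
    na = len(a)
    w_obs = ranks[:na].sum()
    ws = [sum(ranks[list(c)]) for c in combinations(range(len(pooled)), na)]
    lo = sum(w <= w_obs + 1e-9 for w in ws) / len(ws)
    hi = sum(w >= w_obs - 1e-9 for w in ws) / len(ws)
    return min(1.0, 2 * min(lo, hi))


class TestRankSum:
    def test_fully_separated_pairs(self):
        assert rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples_give_one(self):
        assert rank_sum_test([5, 5, 5], [5, 5]) == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            na = int(rng.integers(1, 5))
            nb = int(rng.integers(1, 9 - na))
            a = rng.integers(0, 6, size=na).astype(float)
            b = rng.integers(0, 6, size=nb).astype(float)
            if np.ptp(np.r_[a, b]) == 0:
                continue
            assert rank_sum_test(a, b, mode="exact") == pytest.approx(
                _enumerate_rank_sum_p(a, b), abs=1e-12
            )

    def test_large_shift_detected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(2.0, 1.0, size=50)
        b = rng.normal(0.0, 1.0, size=50)
        assert rank_sum_test(a, b) < 1e-3

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            if rank_sum_test(a, b, mode="normal_approx") < 0.05:
                hits += 1
        assert 0.03 <= hits / reps <= 0.07

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestHypergeometric:
    def test_query_equal_to_set_gives_maximal_fold(self):
        universe = {f"g{i}" for i in range(100)}
        target = {f"g{i}" for i in range(5)}
        df = hypergeometric_enrichment(target, {"s": set(target)}, universe)
        row = df.iloc[0]
        assert row["overlap"] == 5
        assert row["fold"] == pytest.approx(20.0)

    def test_disjoint_set_not_enriched(self):
        universe = {f"g{i}" for i in range(50)}
        df = hypergeometric_enrichment(
            {"g0", "g1"}, {"s": {"g40", "g41"}}, universe
        )
        assert df.iloc[0]["overlap"] == 0
        assert df.iloc[0]["p"] == pytest.approx(1.0)

    def test_matches_brute_force_summation(self):
        universe = {f"g{i}" for i in range(100)}
        annotation = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(5, 15)}  # overlap 5
        df = hypergeometric_enrichment(query, {"s": annotation}, universe)
        brute = sum(
            math.comb(10, k) * math.comb(90, 10 - k) / math.comb(100, 10)
            for k in range(5, 11)
        )
        assert df.iloc[0]["p"] == pytest.approx(brute, abs=1e-10)

    def test_bh_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(6)
        universe = {f"g{i}" for i in range(200)}
        sets = {
            f"s{j}": set(rng.choice(sorted(universe), size=20, replace=False))
            for j in range(8)
        }
        query = set(rng.choice(sorted(universe), size=30, replace=False))
        df = hypergeometric_enrichment(query, sets, universe).sort_values("p")
        assert df["q"].is_monotonic_increasing

    def test_invalid_query_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {"s": {"a"}}, {"a"})
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"zzz"}, {"s": {"a"}}, {"a"})


class TestOverlapCounts:
    def test_small_hand_example(self):
        out = overlap_counts({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
        assert out == {("A",): 1, ("B",): 1, ("A", "B"): 1}

    def test_identical_sets_concentrate_in_full_intersection(self):
        out = overlap_counts({"A": {"x", "y"}, "B": {"x", "y"}})
        assert out == {("A", "B"): 2}

    def test_counts_conserve_union_and_match_signature_tally(self):
        rng = np.random.default_rng(8)
        pool = [f"g{i}" for i in range(60)]
        sets = {
            name: set(rng.choice(pool, size=25, replace=False)) for name in "ABC"
        }
        out = overlap_counts(sets)
        assert sum(out.values()) == len(set().union(*sets.values()))
        for element in set().union(*sets.values()):
            sig = tuple(n for n in "ABC" if element in sets[n])
            assert sig in out


class TestDomains:
    PMDS = [GenomicInterval("chr1", 0, 1000, ".", "p1")]
    HMDS = [GenomicInterval("chr1", 1000, 2000, ".", "h1")]

    def test_fully_inside_pmd(self):
        out = domain_distribution(
            {"r": GenomicInterval("chr1", 100, 200)}, self.PMDS, self.HMDS
        )
        assert out["r"] == "PMD"

    def test_majority_rule_and_pmd_tie_break(self):
        # 60% PMD / 40% HMD
        out = domain_distribution(
            {"r": GenomicInterval("chr1", 700, 1200)}, self.PMDS, self.HMDS
        )
        assert out["r"] == "PMD"
        tie = domain_distribution(
            {"r": GenomicInterval("chr1", 900, 1100)}, self.PMDS, self.HMDS
        )
        assert tie["r"] == "PMD"

    def test_no_overlap_is_other(self):
        out = domain_distribution(
            {"r": GenomicInterval("chr2", 0, 100)}, self.PMDS, self.HMDS
        )
        assert out["r"] == "other"

    def test_group_fractions_sum_to_one(self):
        domains = pd.Series({"a": "PMD", "b": "HMD", "c": "HMD", "d": "other"})
        groups = pd.Series({"a": "C1", "b": "C1", "c": "C5", "d": "C5"})
        frac = group_domain_fractions(domains, groups)
        assert np.allclose(frac.sum(axis=1), 1.0)
        assert frac.loc["C1", "PMD"] == pytest.approx(0.5)


class TestPercentInput:
    @pytest.mark.parametrize(
        "ct_input, ct_sample, expected",
        [(20.0, 20.0, 5.0), (21.0, 20.0, 10.0), (18.0, 20.0, 1.25)],
    )
    def test_formula(self, ct_input, ct_sample, expected):
        assert percent_input(ct_input, ct_sample) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            percent_input(np.nan, 20.0)
        with pytest.raises(ValueError):
            percent_input(20.0, 20.0, input_fraction=0.0)
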