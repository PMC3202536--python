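import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirconnect.cluster import ClusterAssignment
from mirconnect.data import CorrelationTable, GeneSignature, HostPairTable
from mirconnect.signatures import (
    SignatureCounts,
    cluster_enrichment,
    count_gene_set,
    count_signature_correlators,
    em_factor,
    host_pair_correlations,
    hox_cumulative_scores,
    net_score,
    rank_by_factor,
    rank_sum_test,
    significance_tier,
)


def brute_rank_sum_p(x, y):
    """Independent exact two-sided midrank enumeration oracle."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[: len(x)].sum()
    n = len(pooled)
    sums = [sum(c) for c in combinations(ranks, len(x))]
    le = sum(s <= w + 1e-9 for s in sums) / len(sums)
    ge = sum(s >= w - 1e-9 for s in sums) / len(sums)
    return min(1.0, 2 * min(le, ge))


class TestCounting:
    def test_threshold_counts_strict(self):
        sig = GeneSignature("s", {"A": "up", "B": "down"})
        corr = pd.Series({"A": 5.0, "B": -5.0})
        sc = count_signature_correlators(sig, corr, mode="threshold", cutoff=1.0)
        assert (sc.pos_up, sc.neg_down, sc.neg_up, sc.pos_down) == (1, 1, 0, 0)

    def test_boundary_values_uncounted(self):
        assert count_gene_set(["A"], pd.Series({"A": 1.0}), cutoff=1.0) == (0, 0)
        assert count_gene_set(["A"], pd.Series({"A": -1.0}), cutoff=1.0) == (0, 0)

    def test_empty_signature_all_zero(self):
        sig = GeneSignature("s", {})
        sc = count_signature_correlators(sig, pd.Series({"A": 2.0}))
        assert sc == SignatureCounts(0, 0, 0, 0)

    def test_threshold_counts_match_brute_force(self, rng):
        genes = [f"g{i}" for i in range(10)]
        values = pd.Series(rng.normal(scale=2, size=50),
                           index=[f"g{i}" for i in range(50)])
        pos, neg = count_gene_set(genes, values, mode="threshold", cutoff=1.0)
        exp_pos = sum(1 for g in genes if values.get(g, 0) > 1.0)
        exp_neg = sum(1 for g in genes if values.get(g, 0) < -1.0)
        assert (pos, neg) == (exp_pos, exp_neg)

    def test_topn_mode_counts_list_membership(self):
        values = pd.Series({"a": 3.0, "b": 2.0, "c": -1.0, "d": -4.0, "e": 0.5})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pos, neg = count_gene_set(["a", "d", "e"], values, mode="topn", top_n=2)
        assert (pos, neg) == (1, 1)

    def test_absent_genes_count_as_neither(self):
        assert count_gene_set(["zz"], pd.Series({"a": 5.0})) == (0, 0)


class TestScores:
    def test_net_score(self):
        assert net_score(40, 10) == 30
        assert net_score(7, 7) == 0

    def test_em_factor_printed_formula(self):
        counts = SignatureCounts(pos_up=7, neg_up=2, pos_down=1, neg_down=5)
        assert em_factor(counts) == (5 - 1) + (7 - 2) == 9

    def test_em_factor_zero(self):
        assert em_factor(SignatureCounts()) == 0

    def test_fully_epithelial_upper_bound(self):
        counts = SignatureCounts(pos_up=86, neg_up=0, pos_down=0, neg_down=59)
        assert em_factor(counts) == 86 + 59

    def test_em_factor_antisymmetric_under_swaps(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 20, size=4)
            orig = SignatureCounts(pos_up=a, neg_up=b, pos_down=c, neg_down=d)
            label_swap = SignatureCounts(pos_up=c, neg_up=d, pos_down=a, neg_down=b)
            sign_swap = SignatureCounts(pos_up=b, neg_up=a, pos_down=d, neg_down=c)
            assert em_factor(label_swap) == -em_factor(orig)
            assert em_factor(sign_swap) == -em_factor(orig)
            # applying both swaps restores the factor
            both = SignatureCounts(pos_up=d, neg_up=c, pos_down=b, neg_down=a)
            assert em_factor(both) == em_factor(orig)

    def test_rank_by_factor_tie_breaks_by_name(self):
        assert rank_by_factor({"a": 3, "b": -1, "c": 3}) == ["a", "c", "b"]
        assert rank_by_factor({"only": 1.0}) == ["only"]


class TestRankSum:
    @pytest.mark.parametrize("sizes", [(3, 4), (5, 5), (8, 6), (2, 8)])
    def test_matches_enumeration_oracle(self, rng, sizes):
        n1, n2 = sizes
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        assert rank_sum_test(x, y) == pytest.approx(brute_rank_sum_p(x, y), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert rank_sum_test(x, y) == pytest.approx(expected, abs=1e-12)

    def test_extreme_separation_5_vs_20_minimal_p(self):
        x = np.arange(100, 105)       # all larger than the rest
        y = np.arange(20, dtype=float)
        assert rank_sum_test(x, y) == pytest.approx(2 / comb(25, 5), abs=1e-15)

    def test_identical_distribution_gives_p_one(self):
        x = np.ones(5)
        y = np.ones(12)
        assert rank_sum_test(x, y) == 1.0

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=9)
        assert rank_sum_test(x, y) == pytest.approx(
            rank_sum_test(np.exp(x), np.exp(y)), abs=1e-12
        )

    def test_tier_labels(self):
        assert significance_tier(0.005) == "0.01"
        assert significance_tier(5e-5) == "0.0001"
        assert significance_tier(5e-4) == "0.001"
        assert significance_tier(0.5) == "ns"


class TestClusterEnrichment:
    def _assignment(self, labels):
        return ClusterAssignment(labels=labels, cut_height=0.0, share_threshold=12.5)

    def test_enriched_cluster_detected(self, rng):
        labels = {f"m{i}": ("I" if i < 5 else "II") for i in range(25)}
        scores = {f"m{i}": (100.0 + i if i < 5 else float(i)) for i in range(25)}
        df = cluster_enrichment(scores, self._assignment(labels))
        assert df.loc["I", "p_value"] == pytest.approx(2 / comb(25, 5), abs=1e-15)
        assert df.loc["I", "tier"] == "0.0001"

    def test_single_cluster_errors(self):
        labels = {"a": "I", "b": "I"}
        with pytest.raises(ValueError):
            cluster_enrichment({"a": 1.0, "b": 2.0}, self._assignment(labels))


class TestHostPairs:
    def _tables(self):
        data = pd.DataFrame({"spcc": [6.0, 9.0, -9.0], "dpcc": [0.5, 0.4, -0.4]},
                            index=["h1", "h2", "h3"])
        return {"m1": CorrelationTable("m1", data, n_patterns=30)}

    def test_boundary_normalized_value_not_counted_positive(self):
        pairs = HostPairTable([("m1", "h1")])  # sPCC 6/30 = 0.2 exactly
        table, counts = host_pair_correlations(pairs, self._tables(), cutoff=0.2)
        assert counts == {"positive": 0, "negative": 0, "neutral": 1, "missing": 0}

    def test_sign_counting(self):
        pairs = HostPairTable([("m1", "h2"), ("m1", "h3")])
        _, counts = host_pair_correlations(pairs, self._tables(), cutoff=0.2)
        assert counts["positive"] == 1 and counts["negative"] == 1

    def test_absent_gene_flagged_and_excluded(self):
        pairs = HostPairTable([("m1", "missing-gene"), ("m2", "h1")])
        table, counts = host_pair_correlations(pairs, self._tables(), cutoff=0.2)
        assert counts["missing"] == 2
        assert set(table["status"]) == {"missing"}


class TestHoxScores:
    def test_cumulative_sum(self):
        data = pd.DataFrame({"spcc": [2.0, 3.0, -1.0]}, index=["a", "b", "c"])
        tables = {"mx": CorrelationTable("mx", data, n_patterns=30)}
        scores, rankings = hox_cumulative_scores({"HOXA": ["a", "b", "c"]}, tables)
        assert scores.loc["mx", "HOXA"] == pytest.approx(4.0)
        assert rankings["HOXA"] == ["mx"]

    def test_empty_cluster_warns_and_scores_zero(self):
        data = pd.DataFrame({"spcc": [1.0]}, index=["a"])
        tables = {"mx": CorrelationTable("mx", data, n_patterns=30)}
        with pytest.warns(UserWarning):
            scores, _ = hox_cumulative_scores({"empty": []}, tables)
        assert scores.loc["mx", "empty"] == 0.0

    def test_absent_gene_contributes_zero_with_warning(self):
        data = pd.DataFrame({"spcc": [1.0]}, index=["a"])
        tables = {"mx": CorrelationTable("mx", data, n_patterns=30)}
        with pytest.warns(UserWarning):
            scores, _ = hox_cumulative_scores({"HOXA": ["a", "gone"]}, tables)
        assert scores.loc["mx", "HOXA"] == pytest.approx(1.0)
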