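import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirconnect.correlate import (
    PatternSeries,
    build_patterns,
    collapse_and_average,
    direct_pcc,
    pattern_pccs,
    pearson,
    randomized_spcc,
    summed_pcc,
    top_correlators,
)
from mirconnect.data import ProbeGeneMap


def brute_force_spcc(x, y, min_size=30, min_pairs=10):
    """Independent oracle: sort samples by x, slice nested prefixes, sum PCCs."""
    order = np.argsort(-np.asarray(x), kind="stable")
    total, n_def, n_pat = 0.0, 0, len(x) - min_size + 1
    for k in range(min_size, len(x) + 1):
        idx = order[:k]
        xi, yi = np.asarray(x)[idx], np.asarray(y)[idx]
        ok = np.isfinite(xi) & np.isfinite(yi)
        if ok.sum() < max(min_pairs, 2):
            continue
        if np.std(xi[ok]) == 0 or np.std(yi[ok]) == 0:
            continue
        total += stats.pearsonr(xi[ok], yi[ok]).statistic
        n_def += 1
    if n_def == 0 or n_def < n_pat / 2:
        return float("nan")
    return total


class TestPearson:
    def test_perfect_positive(self):
        assert pearson([1, 2, 3], [2, 4, 6], min_pairs=2) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson([1, 2, 3], [3, 2, 1], min_pairs=2) == pytest.approx(-1.0)

    def test_product_moment_value(self):
        # closed-form product-moment on [1,2,3,4] vs [1,3,2,4] gives 0.8
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4], min_pairs=2) == pytest.approx(0.8)

    def test_missing_pairs_dropped(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        x[3] = np.nan
        y[7] = np.nan
        ok = np.isfinite(x) & np.isfinite(y)
        expected = stats.pearsonr(x[ok], y[ok]).statistic
        assert pearson(x, y, min_pairs=5) == pytest.approx(expected, abs=1e-12)

    def test_min_pairs_sentinel(self, rng):
        x = rng.normal(size=8)
        assert np.isnan(pearson(x, x + 1, min_pairs=9))

    def test_zero_variance_sentinel(self):
        assert np.isnan(pearson([1, 1, 1, 1], [1, 2, 3, 4], min_pairs=2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])


class TestPatterns:
    def test_59_samples_min30_gives_30_nested_patterns(self, rng):
        series = build_patterns(rng.normal(size=59), min_size=30)
        assert series.n_patterns == 30
        sizes = [len(p) for p in series]
        assert sizes == list(range(30, 60))
        prev = set()
        for p in series:
            assert prev < set(p.tolist()) or not prev
            prev = set(p.tolist())

    def test_first_pattern_is_top_expression(self, rng):
        values = rng.normal(size=59)
        series = build_patterns(values, min_size=30)
        top = set(np.argsort(-values)[:30].tolist())
        assert set(series.pattern(0).tolist()) == top

    @pytest.mark.parametrize("n,expected", [(31, 2), (30, 1)])
    def test_small_panels(self, rng, n, expected):
        assert build_patterns(rng.normal(size=n), min_size=30).n_patterns == expected

    def test_single_pattern_spcc_equals_plain_pcc(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        series = build_patterns(x, min_size=30)
        assert summed_pcc(x, y, series) == pytest.approx(pearson(x, y), abs=1e-12)

    def test_too_few_samples_errors(self, rng):
        with pytest.raises(ValueError):
            build_patterns(rng.normal(size=10), min_size=30)

    def test_tie_break_by_sample_id_is_deterministic(self):
        values = np.array([1.0, 1.0, 2.0])
        ids = ["b", "a", "c"]
        series = build_patterns(values, min_size=2, sample_ids=ids)
        assert series.order.tolist() == [2, 1, 0]  # c (highest), then a before b


class TestSummedPcc:
    def test_identical_profile_sums_to_pattern_count(self, rng):
        x = rng.normal(size=59)
        series = build_patterns(x, min_size=30)
        assert summed_pcc(x, x.copy(), series) == pytest.approx(30.0)
        assert summed_pcc(x, -x, series) == pytest.approx(-30.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            x = rng.normal(size=59)
            y = rng.normal(size=59)
            series = build_patterns(x, min_size=30)
            assert summed_pcc(x, y, series) == pytest.approx(
                brute_force_spcc(x, y), abs=1e-10
            )

    def test_affine_invariance_and_sign_flip(self, rng):
        x = rng.normal(size=59)
        y = rng.normal(size=59)
        series = build_patterns(x, min_size=30)
        base = summed_pcc(x, y, series)
        assert summed_pcc(x, 3.0 + 2.0 * y, series) == pytest.approx(base, abs=1e-9)
        assert summed_pcc(x, -y, series) == pytest.approx(-base, abs=1e-9)

    def test_bounded_by_pattern_count(self, rng):
        for _ in range(20):
            x = rng.normal(size=59)
            y = rng.normal(size=59)
            series = build_patterns(x, min_size=30)
            assert abs(summed_pcc(x, y, series)) <= series.n_patterns + 1e-12

    def test_vectorised_pattern_pccs_match_loop_with_missing(self, rng):
        x = rng.normal(size=59)
        G = rng.normal(size=(8, 59))
        G[rng.random(G.shape) < 0.05] = np.nan
        series = build_patterns(x, min_size=30)
        R = pattern_pccs(x, G, series, min_pairs=10)
        for gi in range(8):
            for k, idx in enumerate(series):
                expected = pearson(x[idx], G[gi, idx], min_pairs=10)
                if np.isnan(expected):
                    assert np.isnan(R[gi, k])
                else:
                    assert R[gi, k] == pytest.approx(expected, abs=1e-10)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**16),
    n=st.integers(30, 59),
    scale=st.floats(0.1, 10.0),
    shift=st.floats(-5.0, 5.0),
)
def test_spcc_bound_and_affine_invariance_property(seed, n, scale, shift):
    """|sPCC| never exceeds the pattern count and the statistic is invariant
    to positive affine transforms of the gene vector."""
    gen = np.random.default_rng(seed)
    x = gen.normal(size=n)
    y = gen.normal(size=n)
    series = build_patterns(x, min_size=30)
    base = summed_pcc(x, y, series)
    assert abs(base) <= series.n_patterns + 1e-9
    transformed = summed_pcc(x, shift + scale * y, series)
    assert transformed == pytest.approx(base, abs=1e-7)


class TestRandomizedSpcc:
    def test_identity_ordering_recovers_spcc(self, rng):
        x = rng.normal(size=59)
        y = rng.normal(size=59)
        series = build_patterns(x, min_size=30)
        value = randomized_spcc(x, y, orderings=[series.order])
        assert value == pytest.approx(summed_pcc(x, y, series), abs=1e-12)

    def test_reproducible_from_seed(self, rng):
        x = rng.normal(size=59)
        y = rng.normal(size=59)
        a = randomized_spcc(x, y, seed=7)
        b = randomized_spcc(x, y, seed=7)
        c = randomized_spcc(x, y, seed=8)
        assert a == b
        assert a != c

    def test_constant_gene_is_sentinel(self, rng):
        x = rng.normal(size=59)
        assert np.isnan(randomized_spcc(x, np.ones(59), seed=0))


class TestDirectPcc:
    def test_definitional(self, rng):
        x = rng.normal(size=59)
        y = rng.normal(size=59)
        assert direct_pcc(x, y) == pytest.approx(pearson(x, y), abs=1e-12)

    def test_min_pairs_boundary(self, rng):
        x = rng.normal(size=59)
        y = rng.normal(size=59)
        y[40:] = np.nan  # 40 complete pairs
        assert np.isfinite(direct_pcc(x, y, min_pairs=30))
        assert np.isnan(direct_pcc(x, y, min_pairs=50))


class TestCollapse:
    def _pmap(self, rows):
        return ProbeGeneMap(pd.DataFrame(rows, columns=["probe", "gene", "platform"]))

    def test_two_probes_average(self):
        pmap = self._pmap([("p1", "g", "A"), ("p2", "g", "B")])
        values, n = collapse_and_average(
            {"A": pd.Series({"p1": 0.4}), "B": pd.Series({"p2": 0.6})}, pmap
        )
        assert values["g"] == pytest.approx(0.5)
        assert n["g"] == 2

    def test_replicated_platforms_match_single(self, rng):
        probes = [f"p{i}" for i in range(5)]
        vals = pd.Series(rng.normal(size=5), index=probes)
        rows1 = [(p, f"g{i % 3}", "A") for i, p in enumerate(probes)]
        one, _ = collapse_and_average({"A": vals}, self._pmap(rows1))
        rows4 = [(p, f"g{i % 3}", plat) for plat in "ABCD" for i, p in enumerate(probes)]
        four, _ = collapse_and_average(
            {plat: vals for plat in "ABCD"}, self._pmap(rows4)
        )
        pd.testing.assert_series_equal(one, four, check_names=False)

    def test_sentinel_excluded_from_mean(self):
        pmap = self._pmap([("p1", "g", "A"), ("p2", "g", "A"), ("p3", "g", "A")])
        values, n = collapse_and_average(
            {"A": pd.Series({"p1": 0.4, "p2": np.nan, "p3": 0.8})}, pmap
        )
        assert values["g"] == pytest.approx(0.6)
        assert n["g"] == 2

    def test_all_sentinel_gene_absent(self):
        pmap = self._pmap([("p1", "g", "A")])
        values, _ = collapse_and_average({"A": pd.Series({"p1": np.nan})}, pmap)
        assert "g" not in values.index

    def test_platform_mode_weighs_platforms_equally(self):
        pmap = self._pmap([("p1", "g", "A"), ("p2", "g", "A"), ("p3", "g", "B")])
        per_probe = {"A": pd.Series({"p1": 0.0, "p2": 1.0}), "B": pd.Series({"p3": 1.0})}
        flat, _ = collapse_and_average(per_probe, pmap, mode="probe")
        byplat, _ = collapse_and_average(per_probe, pmap, mode="platform")
        assert flat["g"] == pytest.approx(2 / 3)
        assert byplat["g"] == pytest.approx(0.75)


class TestTopCorrelators:
    series = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0, "d": -1.0, "e": -2.0})

    def test_positive(self):
        assert top_correlators(self.series, n=2, sign="positive") == ["a", "b"]

    def test_negative(self):
        assert top_correlators(self.series, n=2, sign="negative") == ["e", "d"]

    def test_overlong_request_warns_and_returns_all_of_sign(self):
        with pytest.warns(UserWarning):
            got = top_correlators(self.series, n=10, sign="positive")
        assert got == ["a", "b", "c"]

    def test_zero_values_belong_to_neither_sign(self):
        s = pd.Series({"a": 0.0, "b": 1.0})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert top_correlators(s, n=5, sign="positive") == ["b"]
            assert top_correlators(s, n=5, sign="negative") == []
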