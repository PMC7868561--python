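import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from circtah import stats as st


def _enumerate_hypergeom_p(universe, a, b, k):
    """Oracle: exhaustive enumeration of all b-subsets of the universe."""
    items = range(universe)
    a_set = set(range(a))
    total = 0
    ge = 0
    for combo in itertools.combinations(items, b):
        total += 1
        if len(a_set.intersection(combo)) >= k:
            ge += 1
    return ge / total


class TestHypergeometricOverlap:
    def test_fully_overlapping_small_sets(self):
        # only one of the C(10,5)=252 draws overlaps completely
        res = st.hypergeometric_overlap(10, 5, 5, 5)
        assert res.p_value == pytest.approx(1 / 252)

    def test_zero_overlap_is_certain(self):
        assert st.hypergeometric_overlap(100, 10, 10, 0).p_value == 1.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            universe = int(rng.integers(4, 13))
            a = int(rng.integers(1, universe + 1))
            b = int(rng.integers(1, universe - 2))
            k = int(rng.integers(0, min(a, b) + 1))
            want = _enumerate_hypergeom_p(universe, a, b, k)
            got = st.hypergeometric_overlap(universe, a, b, k).p_value
            assert got == pytest.approx(want, abs=1e-12)

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValueError):
            st.hypergeometric_overlap(10, 3, 3, 4)


class TestPermutationOverlap:
    def test_reference_equal_to_universe_gives_p_one(self):
        ids = [f"i{k}" for k in range(50)]
        res = st.permutation_overlap(ids, ids[:10], ids, draws=200, seed=0)
        assert res.p_value == 1.0
        assert res.observed == 10

    def test_maximal_enrichment_reaches_minimum_p(self):
        ids = [f"i{k}" for k in range(1000)]
        test = ids[:50]
        res = st.permutation_overlap(ids, test, set(test), draws=1000, seed=0)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_converges_to_exact_hypergeometric(self):
        rng = np.random.default_rng(23)
        universe = [f"i{k}" for k in range(500)]
        ref = set(rng.choice(universe, size=50, replace=False))
        test = list(rng.choice(universe, size=40, replace=False))
        res = st.permutation_overlap(universe, test, ref, draws=20_000, seed=3)
        exact = float(sps.hypergeom.sf(res.observed - 1, 500, 50, 40))
        mc_se = math.sqrt(exact * (1 - exact) / res.draws)
        assert abs(res.p_value - exact) <= 3 * mc_se + 1 / res.draws

    def test_few_draws_warns(self):
        ids = [f"i{k}" for k in range(20)]
        with pytest.warns(UserWarning):
            st.permutation_overlap(ids, ids[:5], ids[:5], draws=10, seed=0)


class TestRankByTstat:
    def test_identical_groups_rank_zero(self):
        a = np.ones((4, 3))
        ranked = st.rank_by_tstat(a, a, [f"f{k}" for k in range(4)])
        assert (ranked["t"] == 0).all()
        # deterministic id tie-break
        assert list(ranked["feature_id"]) == ["f0", "f1", "f2", "f3"]

    def test_shifted_feature_tops_ranking(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 4))
        b = rng.normal(size=(10, 4))
        a[3] += 10
        ranked = st.rank_by_tstat(a, b, [f"f{k}" for k in range(10)])
        assert ranked.loc[0, "feature_id"] == "f3"

    def test_matches_closed_form_on_toy(self):
        a = np.array([[1.0, 2.0, 3.0]])
        b = np.array([[4.0, 6.0, 8.0]])
        ranked = st.rank_by_tstat(a, b, ["f"])
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        want = (a.mean() - b.mean()) / math.sqrt(va / 3 + vb / 3)
        assert ranked.loc[0, "t"] == pytest.approx(want)


def _brute_force_es(scores, is_hit, p):
    """Independent running-sum oracle.

    Returns (high extremum, low extremum); the ES is whichever has the
    larger magnitude, with the sign ambiguous on an exact tie.
    """
    n = len(scores)
    nh = sum(is_hit)
    denom = sum(abs(s) ** p for s, h in zip(scores, is_hit) if h)
    run, series = 0.0, []
    for s, h in zip(scores, is_hit):
        if h:
            run += (abs(s) ** p) / denom if denom > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        series.append(run)
    return max(series), min(series)


def _assert_es_matches(es, hi, lo):
    assert abs(es) == pytest.approx(max(hi, -lo))
    if abs(hi + lo) > 1e-9:
        assert es == pytest.approx(hi if hi > -lo else lo)


class TestGseaPreranked:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(500):
            n = int(rng.integers(5, 51))
            scores = np.sort(rng.normal(size=n))[::-1]
            ids = [f"f{k}" for k in range(n)]
            nh = int(rng.integers(1, n))
            hit_idx = set(rng.choice(n, size=nh, replace=False).tolist())
            fs = {ids[i] for i in hit_idx}
            res = st.gsea_preranked(ids, scores, fs, permutations=5, seed=0)
            hi, lo = _brute_force_es(scores, [i in hit_idx for i in range(n)], 1.0)
            _assert_es_matches(res.es, hi, lo)

    def test_top_block_unweighted_es(self):
        n, nh = 20, 5
        ids = [f"f{k}" for k in range(n)]
        scores = np.linspace(2, 1, n)
        res = st.gsea_preranked(ids, scores, set(ids[:nh]), p=0.0,
                                permutations=10, seed=0)
        hi, lo = _brute_force_es(scores, [i < nh for i in range(n)], 0.0)
        _assert_es_matches(res.es, hi, lo)
        assert res.es > 0.9

    def test_reversing_list_flips_sign(self):
        rng = np.random.default_rng(5)
        scores = np.sort(rng.normal(size=30))[::-1]
        ids = [f"f{k}" for k in range(30)]
        fs = set(ids[:6])
        a = st.gsea_preranked(ids, scores, fs, permutations=10, seed=0)
        b = st.gsea_preranked(ids[::-1], -scores[::-1], fs, permutations=10, seed=0)
        assert a.es == pytest.approx(-b.es)

    def test_null_p_values_are_calibrated(self):
        rng = np.random.default_rng(41)
        ps = []
        scores = np.sort(rng.normal(size=100))[::-1]
        ids = [f"f{k}" for k in range(100)]
        for _ in range(200):
            fs = set(rng.choice(ids, size=10, replace=False).tolist())
            res = st.gsea_preranked(ids, scores, fs, permutations=99,
                                    seed=int(rng.integers(1 << 30)))
            ps.append(res.p_value)
        assert abs(np.mean(np.array(ps) < 0.2) - 0.2) < 0.1

    def test_whole_universe_set_rejected(self):
        ids = ["a", "b"]
        with pytest.raises(ValueError):
            st.gsea_preranked(ids, [1.0, 0.5], set(ids))


class TestDownRegulatedFilter:
    def test_boundary_fold_change_included(self):
        down = st.down_regulated_filter(
            np.array([[10.0]]), np.array([[14.0]]), ["f"]
        )
        assert down == {"f"}

    def test_unchanged_feature_excluded(self):
        down = st.down_regulated_filter(
            np.array([[10.0]]), np.array([[10.0]]), ["f"]
        )
        assert down == set()

    def test_zero_knockdown_mean_included(self):
        down = st.down_regulated_filter(
            np.array([[0.0]]), np.array([[5.0]]), ["f"]
        )
        assert down == {"f"}

    def test_planted_responders_recovered(self, ds_noisefree):
        ds = ds_noisefree
        circ_ids = [c.id for c in ds.circs]
        down = st.down_regulated_filter(
            ds.knockdown_matrix.loc[circ_ids].to_numpy(),
            ds.control_matrix.loc[circ_ids].to_numpy(),
            circ_ids,
        )
        assert down == ds.truth.responsive_ids
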