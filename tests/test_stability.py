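"""Pairwise and k-way stability indices against hand values and brute force."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vimstab.stability import (
    boxplot_summary,
    jaccard_stability,
    kuncheva_stability,
    kway_stability,
    mard,
    spearman_stability,
    truncate,
)

from conftest import make_scores, ranking_from_order


# --- naive reference implementations (direct double loops) -------------------

def naive_spearman(og, oh):
    d = len(og)
    pos_g = {f: i + 1 for i, f in enumerate(og)}
    pos_h = {f: i + 1 for i, f in enumerate(oh)}
    s = sum((pos_g[f] - pos_h[f]) ** 2 for f in og)
    return 1 - 6 * s / (d * (d**2 - 1))


def naive_jaccard(og, oh, cap=100):
    d = min(len(og), cap)
    total = 0.0
    for j in range(1, d):
        a, b = set(og[:j]), set(oh[:j])
        total += len(a & b) / len(a | b)
    return total / (d - 1)


def naive_kuncheva(og, oh, cap=100, chance_d=None):
    d_full = len(og) if chance_d is None else chance_d
    d = min(len(og), cap)
    total = 0.0
    for j in range(1, d):
        r = len(set(og[:j]) & set(oh[:j]))
        total += (r - j**2 / d_full) / (j - j**2 / d_full)
    return total / (d - 1)


def naive_mard(gv, hv):
    terms = []
    for a, b in zip(gv, hv):
        denom = abs(a + b) / 2
        terms.append(0.0 if denom == 0 else abs(a - b) / denom)
    return float(np.mean(terms))


perm_lists = st.permutations(list(range(1, 7)))


class TestHandValues:
    def test_spearman_adjacent_swap(self):
        g = ranking_from_order([1, 2, 3])
        h = ranking_from_order([1, 3, 2])
        assert spearman_stability(g, h) == pytest.approx(1 - 6 * 2 / 24)  # 0.5

    def test_spearman_inverse_order(self):
        g = ranking_from_order([1, 2, 3, 4, 5])
        h = ranking_from_order([5, 4, 3, 2, 1])
        assert spearman_stability(g, h) == pytest.approx(-1.0)

    def test_jaccard_adjacent_swap(self):
        g = ranking_from_order([1, 2, 3])
        h = ranking_from_order([1, 3, 2])
        assert jaccard_stability(g, h) == pytest.approx((1 + 1 / 3) / 2)

    def test_kuncheva_adjacent_swap(self):
        g = ranking_from_order([1, 2, 3])
        h = ranking_from_order([1, 3, 2])
        # j=1 term 1; j=2 term (1 - 4/3)/(2 - 4/3) = -0.5
        assert kuncheva_stability(g, h) == pytest.approx(0.25)

    def test_mard_hand_value(self):
        g = make_scores([0.2, 0.1])
        h = make_scores([0.1, 0.1])
        assert mard(g, h) == pytest.approx((0.1 / 0.15 + 0.0) / 2)

    def test_single_feature_rankings_rejected(self):
        g = ranking_from_order([1])
        for fn in (spearman_stability, jaccard_stability, kuncheva_stability):
            with pytest.raises(ValueError):
                fn(g, g)


class TestTruncation:
    def test_noop_when_d_below_cap(self):
        g = ranking_from_order(range(1, 9))
        assert truncate(g, 100).tolist() == list(range(1, 9))

    def test_caps_long_ranking(self, rng):
        order = rng.permutation(np.arange(1, 5001))
        g = ranking_from_order(order)
        assert truncate(g, 100).tolist() == order[:100].tolist()

    def test_cap_one_returns_top_feature(self):
        g = ranking_from_order([7, 3, 1, 2, 4, 5, 6])
        assert truncate(g, 1).tolist() == [7]

    def test_truncated_indices_use_top_cap_sets(self, rng):
        """d > cap: Jaccard/Kuncheva sums stop at cap; Spearman uses the union."""
        d, cap = 150, 20
        og = rng.permutation(np.arange(1, d + 1))
        oh = rng.permutation(np.arange(1, d + 1))
        g, h = ranking_from_order(og), ranking_from_order(oh)
        assert jaccard_stability(g, h, cap) == pytest.approx(
            naive_jaccard(og.tolist(), oh.tolist(), cap)
        )
        assert kuncheva_stability(g, h, cap) == pytest.approx(
            naive_kuncheva(og.tolist(), oh.tolist(), cap)
        )
        # Spearman union mode: dense re-ranking of the union of top-cap sets
        union = sorted(set(og[:cap]) | set(oh[:cap]))
        pos_g_full = {f: i for i, f in enumerate(og)}
        pos_h_full = {f: i for i, f in enumerate(oh)}
        rg = np.argsort(np.argsort([pos_g_full[f] for f in union])) + 1
        rh = np.argsort(np.argsort([pos_h_full[f] for f in union])) + 1
        dd = len(union)
        expected = 1 - 6 * np.sum((rg - rh) ** 2) / (dd * (dd**2 - 1))
        assert spearman_stability(g, h, cap) == pytest.approx(expected)

    def test_mard_union_size_between_cap_and_twice_cap(self, rng):
        d, cap = 300, 50
        g = make_scores(rng.random(d))
        h = make_scores(rng.random(d))
        # union of two 50-feature top sets has 50..100 members
        v = mard(g, h, cap)
        assert v >= 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("d", [2, 3, 4])
    def test_exhaustive_small_d(self, d):
        ids = list(range(1, d + 1))
        for og in itertools.permutations(ids):
            g = ranking_from_order(og)
            for oh in itertools.permutations(ids):
                h = ranking_from_order(oh)
                assert spearman_stability(g, h) == pytest.approx(
                    naive_spearman(og, oh), abs=1e-12
                )
                if d > 1:
                    assert jaccard_stability(g, h) == pytest.approx(
                        naive_jaccard(og, oh), abs=1e-12
                    )
                    assert kuncheva_stability(g, h) == pytest.approx(
                        naive_kuncheva(og, oh), abs=1e-12
                    )

    def test_exhaustive_d5_against_identity(self):
        ids = list(range(1, 6))
        og = tuple(ids)
        g = ranking_from_order(og)
        for oh in itertools.permutations(ids):
            h = ranking_from_order(oh)
            assert spearman_stability(g, h) == pytest.approx(naive_spearman(og, oh), abs=1e-12)
            assert jaccard_stability(g, h) == pytest.approx(naive_jaccard(og, oh), abs=1e-12)
            assert kuncheva_stability(g, h) == pytest.approx(naive_kuncheva(og, oh), abs=1e-12)

    @pytest.mark.parametrize("d", [6, 7, 8])
    def test_sampled_larger_d(self, d, rng):
        ids = np.arange(1, d + 1)
        for _ in range(60):
            og, oh = rng.permutation(ids), rng.permutation(ids)
            g, h = ranking_from_order(og), ranking_from_order(oh)
            assert spearman_stability(g, h) == pytest.approx(
                naive_spearman(tuple(og), tuple(oh)), abs=1e-12
            )
            assert jaccard_stability(g, h) == pytest.approx(
                naive_jaccard(tuple(og), tuple(oh)), abs=1e-12
            )
            assert kuncheva_stability(g, h) == pytest.approx(
                naive_kuncheva(tuple(og), tuple(oh)), abs=1e-12
            )

    def test_mard_matches_naive_with_ties_and_zeros(self, rng):
        for _ in range(40):
            gv = rng.choice([0.0, 0.05, 0.1, 0.4], size=8)
            hv = rng.choice([0.0, 0.05, 0.1, 0.4], size=8)
            assert mard(make_scores(gv), make_scores(hv)) == pytest.approx(
                naive_mard(gv, hv), abs=1e-12
            )

    def test_spearman_agrees_with_scipy(self, rng):
        from scipy.stats import spearmanr

        for d in (5, 20, 80):
            og = rng.permutation(np.arange(1, d + 1))
            oh = rng.permutation(np.arange(1, d + 1))
            g, h = ranking_from_order(og), ranking_from_order(oh)
            pos_g = np.array([g.position[f] for f in range(1, d + 1)])
            pos_h = np.array([h.position[f] for f in range(1, d + 1)])
            assert spearman_stability(g, h) == pytest.approx(
                spearmanr(pos_g, pos_h).statistic, abs=1e-12
            )


class TestInvariants:
    @given(perm_lists, perm_lists)
    def test_symmetry_and_range(self, og, oh):
        g, h = ranking_from_order(og), ranking_from_order(oh)
        sp = spearman_stability(g, h)
        ja = jaccard_stability(g, h)
        ku = kuncheva_stability(g, h)
        assert sp == pytest.approx(spearman_stability(h, g), abs=1e-14)
        assert ja == pytest.approx(jaccard_stability(h, g), abs=1e-14)
        assert ku == pytest.approx(kuncheva_stability(h, g), abs=1e-14)
        assert -1 - 1e-12 <= sp <= 1 + 1e-12
        assert 0 <= ja <= 1
        assert ku <= 1 + 1e-12

    @given(perm_lists)
    def test_identity(self, og):
        g = ranking_from_order(og)
        assert spearman_stability(g, g) == pytest.approx(1.0)
        assert jaccard_stability(g, g) == pytest.approx(1.0)
        assert kuncheva_stability(g, g) == pytest.approx(1.0)

    @given(perm_lists, perm_lists, perm_lists)
    def test_relabeling_invariance(self, og, oh, relabel):
        mapping = {i + 1: relabel[i] for i in range(len(relabel))}
        g1, h1 = ranking_from_order(og), ranking_from_order(oh)
        g2 = ranking_from_order([mapping[f] for f in og])
        h2 = ranking_from_order([mapping[f] for f in oh])
        assert spearman_stability(g1, h1) == pytest.approx(spearman_stability(g2, h2))
        assert jaccard_stability(g1, h1) == pytest.approx(jaccard_stability(g2, h2))
        assert kuncheva_stability(g1, h1) == pytest.approx(kuncheva_stability(g2, h2))

    def test_mard_identity_is_zero(self, rng):
        g = make_scores(rng.random(9))
        assert mard(g, g) == 0.0

    def test_mard_symmetry_nonnegativity(self, rng):
        g = make_scores(rng.normal(size=9), method="MDA")
        h = make_scores(rng.normal(size=9), method="MDA")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert mard(g, h) == pytest.approx(mard(h, g))
            assert mard(g, h) >= 0

    def test_kuncheva_chance_corrected_mean_near_zero(self, rng):
        """Independent random rankings average ~0 (d=200, cap=100, 2000 pairs)."""
        d, cap = 200, 100
        ids = np.arange(1, d + 1)
        vals = [
            kuncheva_stability(
                ranking_from_order(rng.permutation(ids)),
                ranking_from_order(rng.permutation(ids)),
                cap,
            )
            for _ in range(2000)
        ]
        assert abs(np.mean(vals)) < 0.02


class TestKway:
    def test_pair_count_ten_runs(self, rng):
        runs = [make_scores(rng.random(6)) for _ in range(10)]
        res = kway_stability(runs, "spearman")
        assert len(res.values) == 45 and res.k == 10

    def test_mean_of_three_pairs(self):
        runs = [
            make_scores([3, 2, 1]),
            make_scores([3, 1, 2]),
            make_scores([1, 2, 3]),
        ]
        res = kway_stability(runs, "spearman")
        assert res.mean == pytest.approx(np.mean(res.values))
        assert len(res.values) == 3

    def test_identical_runs_degenerate(self):
        runs = [make_scores([0.5, 0.3, 0.1])] * 4
        for idx, expected in (("spearman", 1.0), ("jaccard", 1.0),
                              ("kuncheva", 1.0), ("mard", 0.0)):
            res = kway_stability(runs, idx)
            assert res.mean == pytest.approx(expected)
            assert res.variance == pytest.approx(0.0)

    def test_fewer_than_two_runs_rejected(self):
        with pytest.raises(ValueError):
            kway_stability([make_scores([1, 2])], "spearman")

    def test_variance_is_sample_variance(self, rng):
        runs = [make_scores(rng.random(8)) for _ in range(5)]
        res = kway_stability(runs, "jaccard")
        assert res.variance == pytest.approx(np.var(res.values, ddof=1))


class TestBoxSummary:
    def test_notch_formula(self):
        # IQR forced to 0.2 with n=100 -> notch height 3.14*0.2/10 = 0.0628
        v = np.concatenate([np.linspace(0, 1, 100)])
        b = boxplot_summary(v)
        expected = 3.14 * b.iqr / 10
        assert b.notch_height == pytest.approx(expected)
        assert b.notch_halfwidth == pytest.approx(expected / 2)

    def test_constant_list(self):
        b = boxplot_summary([0.7] * 10)
        assert b.iqr == 0 and b.outliers == () and b.notch_height == 0
        assert b.whisker_low == b.whisker_high == 0.7

    def test_whiskers_within_fences(self, rng):
        v = rng.standard_t(df=2, size=200)  # heavy tails -> outliers exist
        b = boxplot_summary(v)
        assert b.whisker_low >= b.q1 - 1.5 * b.iqr - 1e-12
        assert b.whisker_high <= b.q3 + 1.5 * b.iqr + 1e-12
        assert all(x < b.q1 - 1.5 * b.iqr or x > b.q3 + 1.5 * b.iqr for x in b.outliers)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_summary([])
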