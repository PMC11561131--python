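"""Samplers: exact uniformity, GW probabilities, Yule splits, Kesten balls."""

from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from phylopatterns import (
    RootedOrderedTree,
    enumerate_all_unrooted,
    enumerate_ordered_trees,
    gw_probability,
    sample_conditioned_gw,
    sample_gw,
    sample_kesten_ball,
    sample_uniform_leaf_labelled,
    sample_yule_harding,
    size_biased,
)
from phylopatterns.samplers import (
    OffspringDistribution,
    TruncatedTreeError,
    sample_conditioned_gw_rejection,
    sample_spine_walk,
)

from conftest import make_rng

X2 = OffspringDistribution.dary(2)
XU = OffspringDistribution.from_dict(
    {0: Fraction(1, 3), 1: Fraction(1, 3), 2: Fraction(1, 3)}
)


class TestOffspringDistribution:
    def test_dary_moments(self):
        for d in (2, 3, 5):
            X = OffspringDistribution.dary(d)
            assert X.mean() == 1 and X.is_critical
            assert X.second_moment() == d
            assert X.p_zero == Fraction(d - 1, d)

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            OffspringDistribution((0, 2), (Fraction(1, 2), Fraction(1, 3)))

    @pytest.mark.parametrize(
        "X,expected",
        [
            (X2, {2: Fraction(1)}),
            (OffspringDistribution.dary(5), {5: Fraction(1)}),
            (XU, {1: Fraction(1, 3), 2: Fraction(2, 3)}),
        ],
    )
    def test_size_biased(self, X, expected):
        Xs = size_biased(X)
        assert dict(zip(Xs.support, Xs.probabilities)) == expected

    def test_size_biased_needs_positive_mean(self):
        with pytest.raises(ValueError):
            size_biased(OffspringDistribution((0,), (Fraction(1),)))


class TestUnconditionedGW:
    def test_out_degrees_stay_in_support(self):
        rng = make_rng(10)
        done = 0
        while done < 200:
            try:
                t = sample_gw(X2, rng, max_vertices=500)
            except TruncatedTreeError:
                continue  # heavy tail: a critical tree occasionally blows up
            assert set(t.out_degrees) <= {0, 2}
            done += 1

    def test_truncation_is_signalled(self):
        rng = make_rng(11)
        with pytest.raises(TruncatedTreeError):
            for _ in range(5000):
                sample_gw(X2, rng, max_vertices=5)
                # a critical GW tree exceeds any fixed budget eventually

    def test_atom_probabilities(self):
        # P(single vertex) = 1 - 1/d and P(cherry) = (1/2)(1/2)^2 for d=2
        rng = make_rng(12)
        reps = 10_000
        single = cherry = 0
        for _ in range(reps):
            try:
                t = sample_gw(X2, rng, max_vertices=10_000)
            except TruncatedTreeError:
                continue  # counts as neither atom
            if t.out_degrees == (0,):
                single += 1
            elif t.out_degrees == (2, 0, 0):
                cherry += 1
        for obs, p in [(single, 0.5), (cherry, 0.125)]:
            se = (p * (1 - p) / reps) ** 0.5
            assert abs(obs / reps - p) <= 3 * se

    def test_gw_probability_constant_over_7_vertex_binary_trees(self):
        trees = enumerate_ordered_trees(7, (0, 2))
        assert len(trees) == 5
        probs = {gw_probability(t, X2) for t in trees}
        assert probs == {Fraction(1, 2) ** 3 * Fraction(1, 2) ** 4}


class TestConditionedGW:
    def test_single_vertex(self):
        t = sample_conditioned_gw(X2, 1, make_rng(20))
        assert t.out_degrees == (0,)

    def test_impossible_size_names_congruence(self):
        with pytest.raises(ValueError, match="mod 2"):
            sample_conditioned_gw(X2, 4, make_rng(21))

    def test_ternary_unique_four_vertex_tree(self):
        X3 = OffspringDistribution.dary(3)
        t = sample_conditioned_gw(X3, 4, make_rng(22))
        assert t.out_degrees == (3, 0, 0, 0)

    def test_uniform_over_7_vertex_trees(self):
        rng = make_rng(23)
        trees = [t.out_degrees for t in enumerate_ordered_trees(7, (0, 2))]
        counts = Counter(
            sample_conditioned_gw(X2, 7, rng).out_degrees for _ in range(20_000)
        )
        assert set(counts) == set(trees)
        assert stats.chisquare([counts[t] for t in trees]).pvalue > 1e-3

    def test_cycle_lemma_agrees_with_rejection_oracle(self):
        # both samplers target the same law; compare empirical distributions
        rng = make_rng(24)
        trees = [t.out_degrees for t in enumerate_ordered_trees(7, (0, 2))]
        a = Counter(sample_conditioned_gw(X2, 7, rng).out_degrees for _ in range(5000))
        b = Counter(
            sample_conditioned_gw_rejection(X2, 7, rng).out_degrees
            for _ in range(5000)
        )
        obs = np.array([[a[t] for t in trees], [b[t] for t in trees]])
        assert stats.chi2_contingency(obs).pvalue > 1e-3

    def test_general_law_matches_exact_conditional_distribution(self):
        # for X uniform on {0,1,2}, P(T = tau | #T = 5) is computable exactly
        rng = make_rng(25)
        atoms = {
            t.out_degrees: gw_probability(t, XU)
            for t in enumerate_ordered_trees(5, (0, 1, 2))
        }
        total = sum(atoms.values())
        reps = 20_000
        counts = Counter(
            sample_conditioned_gw(XU, 5, rng).out_degrees for _ in range(reps)
        )
        expected = [float(p / total) * reps for p in atoms.values()]
        observed = [counts[t] for t in atoms]
        assert stats.chisquare(observed, expected).pvalue > 1e-3

    def test_out_degrees_in_support_and_size(self):
        rng = make_rng(26)
        for n in (5, 21, 201):
            t = sample_conditioned_gw(X2, n, rng)
            assert t.n_vertices == n and set(t.out_degrees) <= {0, 2}


class TestUniformLeafLabelled:
    def test_small_cases(self):
        assert sample_uniform_leaf_labelled(2, 2, make_rng(30)).n_leaves == 2
        t3 = sample_uniform_leaf_labelled(3, 2, make_rng(31))
        assert t3.canonical_code() in {
            t.canonical_code() for t in enumerate_all_unrooted(3)
        }

    def test_invalid_leaf_count_rejected(self):
        with pytest.raises(ValueError):
            sample_uniform_leaf_labelled(5, 3, make_rng(32))

    def test_uniform_over_b5(self):
        rng = make_rng(33)
        codes = [t.canonical_code() for t in enumerate_all_unrooted(5)]
        counts = Counter(
            sample_uniform_leaf_labelled(5, 2, rng).canonical_code()
            for _ in range(15_000)
        )
        assert set(counts) == set(codes)
        assert stats.chisquare([counts[c] for c in codes]).pvalue > 1e-3

    def test_exact_multinomial_at_n4(self):
        # three topologies; per-cell exact binomial test at alpha 1e-3/3
        rng = make_rng(34)
        codes = [t.canonical_code() for t in enumerate_all_unrooted(4)]
        reps = 6000
        counts = Counter(
            sample_uniform_leaf_labelled(4, 2, rng).canonical_code()
            for _ in range(reps)
        )
        for c in codes:
            assert stats.binomtest(counts[c], reps, 1 / 3).pvalue > 1e-3 / 3


class TestYuleHarding:
    def test_two_and_three_leaves(self):
        assert sample_yule_harding(2, make_rng(40)).n_leaves == 2
        t = sample_yule_harding(3, make_rng(41))
        assert t.n_leaves == 3 and t.n_vertices == 4

    def test_three_leaf_root_split_balanced(self):
        # rooted 3-leaf tree: the two root subtrees have sizes {1, 2} and
        # which side is the singleton is a fair coin
        rng = make_rng(42)
        reps = 9000
        ones = sum(
            1
            for _ in range(reps)
            if sample_yule_harding(3, rng, keep_root=True).out_degrees[1] == 0
        )
        se = (0.5 * 0.5 / reps) ** 0.5
        assert abs(ones / reps - 0.5) <= 3 * se

    def test_root_split_uniform_n50(self):
        from phylopatterns.experiments import yule_split_test

        _, p = yule_split_test(50, 4000, 43)
        assert p > 1e-3

    def test_unrooted_labels_are_permutation(self):
        t = sample_yule_harding(20, make_rng(44))
        assert sorted(t.leaf_labels.values()) == list(range(1, 21))


class TestKestenBall:
    def test_radius_zero_is_single_spine_vertex(self):
        kb = sample_kesten_ball(X2, 0, make_rng(50))
        assert kb.tree.out_degrees == (0,) and kb.spine == ((),)

    def test_binary_spine_has_one_offspine_child_each(self):
        kb = sample_kesten_ball(X2, 5, make_rng(51))
        assert len(kb.spine) == 6
        degmap = kb.tree.out_degree_map()
        for addr in kb.spine[:-1]:
            assert degmap[addr] == 2  # X* is a point mass at 2
        assert kb.spine_out_edges == (1, 2, 3, 4, 5)

    def test_spine_is_root_path(self):
        kb = sample_kesten_ball(X2, 3, make_rng(52))
        for a, b in zip(kb.spine, kb.spine[1:]):
            assert len(b) == len(a) + 1 and b[: len(a)] == a

    def test_non_critical_law_rejected(self):
        bad = OffspringDistribution((0, 3), (Fraction(1, 2), Fraction(1, 2)))
        with pytest.raises(ValueError, match="critical"):
            sample_kesten_ball(bad, 2, make_rng(53))

    def test_spine_walk_drift(self):
        # S_k / k -> E(X*) - 1; for the uniform {0,1,2} law E(X*) = 5/3
        rng = make_rng(54)
        k = 1000
        walk = sample_spine_walk(XU, k, rng)
        drift = float(size_biased(XU).mean() - 1)
        sd_inc = float(size_biased(XU).variance()) ** 0.5
        assert abs(walk[-1] / k - drift) <= 3 * sd_inc / k**0.5
        # and for d-ary laws the walk is deterministic: S_k = k(d-1)
        assert sample_spine_walk(X2, 10, rng) == [i + 1 for i in range(10)]


class TestDeterminism:
    def test_identical_seeds_identical_trees(self):
        for sampler in (
            lambda r: sample_uniform_leaf_labelled(30, 2, r).canonical_code(),
            lambda r: sample_yule_harding(30, r).canonical_code(),
            lambda r: sample_conditioned_gw(X2, 31, r).out_degrees,
            lambda r: sample_kesten_ball(X2, 3, r).tree.out_degrees,
        ):
            a = sampler(make_rng(60))
            b = sampler(make_rng(60))
            assert a == b
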