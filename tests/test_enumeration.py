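"""Exact counting formulas: identities, oracles, asymptotics."""

import itertools
from fractions import Fraction
from math import factorial

import pytest

from phylopatterns import enumerate_all_unrooted
from phylopatterns.enumeration import (
    W_by_summation,
    W_density,
    W_density_float,
    W_identity,
    W_symmetry_constant,
    catalan,
    count_forests,
    count_rooted_binary,
    count_unrooted_binary,
    count_unrooted_dary,
    double_factorial,
    egf_rooted_coefficient,
    ordered_dary_count,
    remark_identity_ordered_vs_unrooted,
    snowflake_density,
    snowflake_density_float,
    snowflake_pairs,
    snowflake_symmetry_constant,
    verify_forest_decomposition,
)


def rooted_forest_count_oracle(n: int, k: int) -> int:
    """N(n, k) by brute force: sum over partitions of {1..n} into k blocks of
    the product of rooted-tree counts per block, with rooted counts obtained
    from the exhaustive unrooted generator (a rooted tree on b leaves is an
    unrooted tree on b+1 leaves with a distinguished extra leaf)."""

    def partitions(items, k):
        if k == 1:
            yield [items]
            return
        if len(items) < k:
            return
        first, rest = items[0], items[1:]
        for p in partitions(rest, k - 1):
            yield [[first]] + p
        for p in partitions(rest, k):
            for i in range(len(p)):
                yield p[:i] + [[first] + p[i]] + p[i + 1 :]

    def rooted_count(b: int) -> int:
        if b == 1:
            return 1
        return sum(1 for _ in enumerate_all_unrooted(b + 1))

    return sum(
        int(
            __import__("math").prod(rooted_count(len(block)) for block in p)
        )
        for p in partitions(list(range(1, n + 1)), k)
    )


class TestBasicCounts:
    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 1), (4, 3), (5, 15), (6, 105)])
    def test_unrooted_binary_small_values(self, n, expected):
        assert count_unrooted_binary(n) == expected

    def test_both_printed_forms_agree_up_to_200(self):
        # the factorial-quotient and double-factorial forms are both
        # evaluated inside count_unrooted_binary and asserted equal
        for n in range(2, 201):
            count_unrooted_binary(n)

    @pytest.mark.parametrize("n", [1, 2, 4, 5, 10])
    def test_rooted_equals_unrooted_shifted(self, n):
        assert count_rooted_binary(n) == count_unrooted_binary(n + 1)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            count_unrooted_binary(1)
        with pytest.raises(ValueError):
            count_rooted_binary(0)
        with pytest.raises(ValueError):
            count_forests(0, 1)
        with pytest.raises(ValueError):
            count_forests(3, 0)


class TestForestCounts:
    def test_diagonal_is_one(self):
        for n in range(1, 31):
            assert count_forests(n, n) == 1

    def test_above_diagonal_is_zero(self):
        assert count_forests(11, 12) == 0

    @pytest.mark.parametrize("n", range(1, 13))
    def test_one_and_two_tree_forests_count_rooted_trees(self, n):
        assert count_forests(n, 1) == count_rooted_binary(n)
        if n >= 2:
            assert count_forests(n, 2) == count_rooted_binary(n)

    @pytest.mark.parametrize("n,k", [(3, 2), (4, 2), (4, 3), (5, 2), (5, 4)])
    def test_against_brute_force_partition_oracle(self, n, k):
        assert count_forests(n, k) == rooted_forest_count_oracle(n, k)

    @pytest.mark.parametrize("n", list(range(1, 41)))
    def test_forest_decomposition_identity(self, n):
        res = verify_forest_decomposition(n)
        assert res.holds and res.lhs == res.rhs


class TestSnowflakeCounts:
    def test_symmetry_constant_is_computed(self):
        assert snowflake_symmetry_constant() == factorial(12) // (2**9 * factorial(3))
        assert snowflake_symmetry_constant() == 155925

    def test_below_twelve_leaves_no_pairs(self):
        assert snowflake_pairs(11) == 0
        assert snowflake_density(11) == 0

    def test_twelve_leaves(self):
        assert snowflake_pairs(12) == 155925
        assert snowflake_density(12) == Fraction(155925, 654729075)

    def test_pairs_equal_forest_times_constant_up_to_60(self):
        for n in range(12, 61):
            assert snowflake_pairs(n) == count_forests(n, 12) * snowflake_symmetry_constant()

    def test_density_closed_form_prefactor_is_four(self):
        for n in (12, 15, 30):
            ratio = Fraction(snowflake_pairs(n), count_unrooted_binary(n))
            fac = Fraction(factorial(2 * n - 13), factorial(2 * n - 4)) * Fraction(
                factorial(n - 2), factorial(n - 12)
            )
            assert ratio / fac == 4

    def test_asymptotic_density_over_n(self):
        # leading finite-size correction is (1 - 29/n)
        val = snowflake_density_float(10**6) / 10**6
        assert abs(val - 2**-7) <= 1e-6  # one unit in the 4th sig. figure

    def test_float_matches_exact_at_moderate_n(self):
        exact = float(snowflake_density(200))
        assert abs(snowflake_density_float(200) - exact) < 1e-12


class TestDistantPairCounts:
    def test_below_22_leaves_zero(self):
        assert W_by_summation(21) == 0 and W_identity(21) == 0

    def test_at_22_single_term(self):
        assert W_by_summation(22) == factorial(22) // 2**16
        assert W_identity(22) == W_symmetry_constant() * count_forests(23, 23)

    def test_summation_equals_identity_22_to_60(self):
        for n in range(22, 61):
            assert W_by_summation(n) == W_identity(n)

    def test_density_times_b_equals_w(self):
        for n in (22, 30, 45, 60):
            assert W_density(n) * count_unrooted_binary(n) == W_by_summation(n)

    def test_closed_form_prefactor_is_sixteen(self):
        for n in (22, 30):
            ratio = Fraction(W_by_summation(n), count_unrooted_binary(n))
            fac = Fraction(factorial(2 * n - 22), factorial(2 * n - 4)) * Fraction(
                factorial(n - 2), factorial(n - 22)
            )
            assert ratio / fac == 16

    def test_asymptotic_density_over_n_squared(self):
        # leading finite-size correction is (1 - 117.5/n)
        val = W_density_float(10**6) / 10**12
        assert abs(val - 2**-14) <= 1e-8  # one unit in the 4th sig. figure


class TestAsymptoticMonotonicity:
    def test_scaled_densities_increase_to_one(self):
        grid = [30, 100, 300, 1000, 3000, 10**4, 10**5, 10**6]
        s_vals = [snowflake_density_float(n) * 128 / n for n in grid]
        w_vals = [W_density_float(n) * 2**14 / n**2 for n in grid]
        # leading corrections: 1 - 29/n (snowflake) and 1 - 117.5/n (pairs)
        for seq, lead in ((s_vals, 29.0), (w_vals, 117.5)):
            assert all(a < b for a, b in zip(seq, seq[1:]))
            assert seq[-1] < 1 and 1 - seq[-1] < 1.5 * lead / 10**6


class TestOrderedUnrootedCorrespondence:
    @pytest.mark.parametrize("n", [3, 5, 7, 9, 12])
    def test_binary_case(self, n):
        assert remark_identity_ordered_vs_unrooted(2, n)
        # spot-check the ingredients: Catalan and double factorial
        assert ordered_dary_count(n - 1, 2) == catalan(n - 2)
        assert count_unrooted_binary(n) == double_factorial(2 * n - 5)

    @pytest.mark.parametrize("n", [4, 6])
    def test_ternary_case_against_exhaustive(self, n):
        assert remark_identity_ordered_vs_unrooted(3, n)

    def test_ternary_exhaustive_count(self):
        assert count_unrooted_dary(4, 3) == 1
        # solved from the identity: |T~_6| = 3 * 6! / (6 * (3!)^2) = 10
        assert count_unrooted_dary(6, 3) == 10

    def test_impossible_leaf_count_rejected(self):
        with pytest.raises(ValueError):
            remark_identity_ordered_vs_unrooted(3, 5)

    def test_fuss_catalan_matches_exhaustive_ordered_generator(self):
        from phylopatterns import enumerate_ordered_trees

        for d, leaves in [(2, 4), (2, 5), (3, 5), (3, 7)]:
            k = (leaves - 1) // (d - 1)
            m = d * k + 1
            assert ordered_dary_count(leaves, d) == len(
                enumerate_ordered_trees(m, (0, d))
            )


class TestGeneratingFunctionOracle:
    def test_egf_coefficients_match_rooted_counts(self):
        # series coefficients of 1 - sqrt(1 - 2x) against R(n)/n!
        for n in range(1, 21):
            assert egf_rooted_coefficient(n) == Fraction(
                count_rooted_binary(n), factorial(n)
            )
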