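"""Exact counting formulas for binary phylogenetic trees and snowflakes.

Everything here is evaluated with arbitrary-precision integers and
:class:`fractions.Fraction` — no floating point enters any identity check.
Floats (via ``scipy.special.gammaln``) are used only in the ``*_float``
asymptotic evaluators, where factorials at ``n ~ 10**6`` would be
impractically large.

Notation (all for unrooted binary phylogenetic trees on ``n`` labelled
leaves unless stated otherwise):

* ``B(n) = (2n-4)! / ((n-2)! 2^(n-2)) = (2n-5)!!`` — number of trees;
* ``R(n) = B(n+1)`` — number of rooted binary trees;
* ``N(n, k) = (2n-k-1)! / ((n-k)! (k-1)! 2^(n-k))`` — number of forests of
  ``k`` rooted binary trees whose leaf sets partition ``1..n``;
* ``|S(n)| = N(n, 12) * 12!/(2^9 * 3!)`` — number of (tree, vertex) pairs
  where the vertex is the central vertex of a snowflake;
* ``W(n)`` — number of (tree, v1, v2) triples with both vertices snowflake
  centres at distance >= 5 from each other.

The snowflake is the pattern with a central vertex, six interior vertices at
distance 2, and twelve hanging rooted subtrees; a vertex is a snowflake
centre iff its distance to every leaf is at least 3.
"""

from __future__ import annotations

from collections import namedtuple
from fractions import Fraction
from math import comb, exp, factorial

from scipy.special import gammaln

__all__ = [
    "count_unrooted_binary",
    "count_rooted_binary",
    "count_forests",
    "verify_forest_decomposition",
    "snowflake_pairs",
    "snowflake_symmetry_constant",
    "snowflake_density",
    "snowflake_density_float",
    "expected_snowflake_centers",
    "W_by_summation",
    "W_identity",
    "W_symmetry_constant",
    "W_density",
    "W_density_float",
    "catalan",
    "ordered_dary_count",
    "count_unrooted_dary",
    "remark_identity_ordered_vs_unrooted",
    "egf_rooted_coefficient",
    "double_factorial",
]


def double_factorial(m: int) -> int:
    """``m!! = m (m-2) (m-4) ...``; equals 1 for m <= 1 (including odd negatives)."""
    out = 1
    while m > 1:
        out *= m
        m -= 2
    return out


def count_unrooted_binary(n: int) -> int:
    """``B(n)``, the number of unrooted binary phylogenetic trees on ``n`` leaves.

    Both printed forms — the factorial quotient and the double factorial —
    are evaluated and must agree.
    """
    if n < 2:
        raise ValueError("B(n) requires n >= 2")
    form1 = factorial(2 * n - 4) // (factorial(n - 2) * 2 ** (n - 2))
    form2 = double_factorial(2 * n - 5)
    if form1 != form2:
        raise AssertionError(f"B({n}): factorial and double-factorial forms differ")
    return form1


def count_rooted_binary(n: int) -> int:
    """``R(n) = B(n+1)``, the number of rooted binary trees on ``n`` leaves."""
    if n < 1:
        raise ValueError("R(n) requires n >= 1")
    return count_unrooted_binary(n + 1)


def count_forests(n: int, k: int) -> int:
    """``N(n, k)``: forests of ``k`` rooted binary trees partitioning ``1..n``.

    Zero when ``k > n``; satisfies ``N(n,1) = N(n,2) = R(n)`` and ``N(n,n) = 1``.
    """
    if n < 1 or k < 1:
        raise ValueError("N(n, k) requires n >= 1 and k >= 1")
    if k > n:
        return 0
    return factorial(2 * n - k - 1) // (
        factorial(n - k) * factorial(k - 1) * 2 ** (n - k)
    )


ForestDecomposition = namedtuple("ForestDecomposition", ["holds", "lhs", "rhs"])


def verify_forest_decomposition(n: int) -> ForestDecomposition:
    """Check ``B(n+2) = sum_{k=1}^n k! N(n, k)`` exactly.

    The identity reflects the bijection between trees on ``n + 2`` leaves and
    ordered forests attached to the path between the two extra leaves.
    """
    if n < 1:
        raise ValueError("requires n >= 1")
    lhs = count_unrooted_binary(n + 2)
    rhs = sum(factorial(k) * count_forests(n, k) for k in range(1, n + 1))
    return ForestDecomposition(lhs == rhs, lhs, rhs)


def snowflake_symmetry_constant() -> int:
    """``12!/(2^9 * 3!)`` — arrangements of the 12 hanging subtrees of a
    snowflake, by orbit–stabilizer (the stabilizer has order ``2^9 * 3!``)."""
    return factorial(12) // (2**9 * factorial(3))


def snowflake_pairs(n: int) -> int:
    """``|S(n)| = N(n, 12) * 12!/(2^9 * 3!)``; zero for ``n < 12``."""
    if n < 1:
        raise ValueError("requires n >= 1")
    if n < 12:
        return 0
    return count_forests(n, 12) * snowflake_symmetry_constant()


def snowflake_density(n: int) -> Fraction:
    """``|S(n)|/B(n)`` in lowest terms; equals ``E(X_n)``, the expected number
    of snowflake centres in a uniform tree, since ``S(n)`` counts (tree,
    centre) pairs.

    The direct ratio and the closed form
    ``4 (2n-13)!/(2n-4)! (n-2)!/(n-12)!`` are both evaluated and must agree.
    Asymptotically the density is ``~ n 2^-7``.
    """
    if n < 12:
        return Fraction(0)
    ratio = Fraction(snowflake_pairs(n), count_unrooted_binary(n))
    closed = (
        4
        * Fraction(factorial(2 * n - 13), factorial(2 * n - 4))
        * Fraction(factorial(n - 2), factorial(n - 12))
    )
    if ratio != closed:
        raise AssertionError(f"snowflake density closed form fails at n={n}")
    return ratio


#: ``E(X_n)`` — alias emphasising the probabilistic reading of the density.
expected_snowflake_centers = snowflake_density


def snowflake_density_float(n: int) -> float:
    """Float evaluation of ``|S(n)|/B(n)`` via log-Gamma, stable for huge n."""
    if n < 12:
        return 0.0
    log = (
        gammaln(2 * n - 12)
        - gammaln(2 * n - 3)
        + gammaln(n - 1)
        - gammaln(n - 11)
    )
    return 4.0 * exp(log)


def W_symmetry_constant() -> int:
    """``22!/2^16`` — attachments of the 22 hanging subtrees in the
    two-snowflake decomposition, by orbit–stabilizer."""
    return factorial(22) // 2**16


def W_by_summation(n: int) -> int:
    """``W(n)`` by the forest decomposition along the path between the two
    centres: ``sum_{i=0}^{n-22} B(i+2) C(n,i) N(n-i, 22) 22!/2^16``.

    Zero for ``n < 22``.  The ``i = 0`` term uses the convention ``B(2) = 1``
    (the empty forest on the path).
    """
    if n < 22:
        return 0
    c = W_symmetry_constant()
    total = 0
    for i in range(0, n - 22 + 1):
        total += (
            count_unrooted_binary(i + 2)
            * comb(n, i)
            * count_forests(n - i, 22)
            * c
        )
    return total


def W_identity(n: int) -> int:
    """``W(n) = (22!/2^16) N(n+1, 23)`` — the closed form obtained from the
    generating function ``r(x) = 1 - sqrt(1 - 2x)`` of rooted binary trees."""
    if n < 22:
        return 0
    return W_symmetry_constant() * count_forests(n + 1, 23)


def W_density(n: int) -> Fraction:
    """``W(n)/B(n) = 16 (2n-22)!/(2n-4)! (n-2)!/(n-22)!`` in lowest terms.

    Asymptotically ``~ n^2 2^-14``; this is the distance-separated part of
    ``E(X_n^2)``.
    """
    if n < 22:
        return Fraction(0)
    return (
        16
        * Fraction(factorial(2 * n - 22), factorial(2 * n - 4))
        * Fraction(factorial(n - 2), factorial(n - 22))
    )


def W_density_float(n: int) -> float:
    """Float evaluation of ``W(n)/B(n)`` via log-Gamma, stable for huge n."""
    if n < 22:
        return 0.0
    log = (
        gammaln(2 * n - 21)
        - gammaln(2 * n - 3)
        + gammaln(n - 1)
        - gammaln(n - 21)
    )
    return 16.0 * exp(log)


# ---------------------------------------------------------------------------
# Ordered d-ary counts and the ordered/unrooted correspondence
# ---------------------------------------------------------------------------


def catalan(k: int) -> int:
    if k < 0:
        raise ValueError("requires k >= 0")
    return comb(2 * k, k) // (k + 1)


def ordered_dary_count(n_leaves: int, d: int = 2) -> int:
    """Number of ordered d-ary trees with ``n_leaves`` leaves (Fuss–Catalan).

    With ``k`` internal vertices there are ``(d-1)k + 1`` leaves and the count
    is ``C(dk, k) / ((d-1)k + 1)``; for ``d = 2`` this is the Catalan number
    ``C_{n_leaves - 1}``.
    """
    if d < 2:
        raise ValueError("requires d >= 2")
    if n_leaves < 1:
        raise ValueError("requires n_leaves >= 1")
    if (n_leaves - 1) % (d - 1) != 0:
        return 0
    k = (n_leaves - 1) // (d - 1)
    return comb(d * k, k) // ((d - 1) * k + 1)


def count_unrooted_dary(n: int, d: int = 2, force: bool = False) -> int:
    """Number of leaf-labelled d-ary trees on ``n`` leaves.

    For ``d = 2`` this is ``B(n)``; for ``d > 2`` the trees are enumerated
    exhaustively (small ``n`` only).
    """
    if d == 2:
        return count_unrooted_binary(n)
    from .trees import enumerate_all_unrooted

    return sum(1 for _ in enumerate_all_unrooted(n, d=d, force=force))


def remark_identity_ordered_vs_unrooted(d: int, n: int) -> bool:
    """Check ``|T_{n-1}| n! = |T~_n| n (d!)^{(n-2)/(d-1)}``.

    ``|T_{n-1}|`` counts ordered d-ary trees on ``n - 1`` leaves and
    ``|T~_n|`` the leaf-labelled unrooted ones on ``n`` leaves; the identity
    expresses the double counting behind the graft-and-label construction of
    a uniform unrooted tree.  ``n`` must satisfy ``(n - 2) % (d - 1) == 0``,
    the condition for d-ary trees with ``n`` leaves to exist (always true
    for ``d = 2``).
    """
    if n < d + 1 or (n - 2) % (d - 1) != 0:
        raise ValueError(
            f"no {d}-ary tree has {n} leaves: need n >= d+1 and "
            f"(n - 2) % (d - 1) == 0"
        )
    lhs = ordered_dary_count(n - 1, d) * factorial(n)
    rhs = count_unrooted_dary(n, d) * n * factorial(d) ** ((n - 2) // (d - 1))
    return lhs == rhs


# ---------------------------------------------------------------------------
# Generating-function cross-check oracle
# ---------------------------------------------------------------------------


def egf_rooted_coefficient(n: int) -> Fraction:
    """``[x^n] (1 - sqrt(1 - 2x))`` as an exact rational.

    ``1 - sqrt(1 - 2x)`` is the exponential generating function of rooted
    binary phylogenetic trees, so this coefficient must equal ``R(n)/n!``.
    Computed independently via the generalized binomial series of
    ``(1 - 2x)^(1/2)``.
    """
    if n < 1:
        raise ValueError("requires n >= 1")
    # C(1/2, n) = prod_{j=0}^{n-1} (1/2 - j) / n!
    num = Fraction(1)
    for j in range(n):
        num *= Fraction(1, 2) - j
    binom_half = num / factorial(n)
    return -binom_half * (-2) ** n
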