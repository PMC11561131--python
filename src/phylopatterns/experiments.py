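"""Seeded Monte-Carlo experiments tying the samplers to the exact formulas.

Every experiment is reproducible bit-for-bit from its ``(parameters, seed)``
pair: each replicate runs on its own child generator spawned from
``numpy.random.SeedSequence(seed)``, so replicate streams are independent
and the replicate count can be changed without reshuffling earlier draws.

Estimates are reported with their Monte-Carlo standard error (sample
standard deviation over sqrt(replicates)); the package's own acceptance
bands are 3 standard errors wherever an exact value exists, and
property-based (monotonicity, bounds) where the theory provides only a
limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import enumeration
from .patterns import (
    PatternTree,
    count_snowflake_centers,
    is_realizable,
    occurs,
    snowflake_pattern,
)
from .samplers import (
    OffspringDistribution,
    sample_conditioned_gw,
    sample_kesten_ball,
    sample_uniform_leaf_labelled,
    sample_yule_harding,
)

__all__ = [
    "MCEstimate",
    "CurveResult",
    "mc_mean_snowflake_centers",
    "mc_second_moment_snowflake_centers",
    "mc_zero_probability",
    "mc_pattern_curve",
    "ball_tv_distance",
    "yule_split_test",
]


@dataclass(frozen=True)
class MCEstimate:
    """A Monte-Carlo point estimate with its standard error."""

    estimate: float
    se: float
    reps: int
    seed: int

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class CurveResult:
    """Per-n Monte-Carlo estimates of a pattern-occurrence probability."""

    model: str
    pattern: str
    d: int
    n_grid: Tuple[int, ...]
    estimates: List[MCEstimate]
    short_circuit: bool = False  # pattern not realizable: curve exactly 0

    def __post_init__(self):
        if list(self.n_grid) != sorted(set(self.n_grid)):
            raise ValueError("n_grid must be strictly increasing")

    def frequencies(self) -> List[float]:
        return [e.estimate for e in self.estimates]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model,
                "pattern": self.pattern,
                "d": self.d,
                "n": list(self.n_grid),
                "estimate": [e.estimate for e in self.estimates],
                "se": [e.se for e in self.estimates],
                "reps": [e.reps for e in self.estimates],
                "seed": [e.seed for e in self.estimates],
            }
        )


def _child_rngs(seed: int, reps: int) -> List[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(reps)]


def _summarise(values: np.ndarray, seed: int) -> MCEstimate:
    reps = len(values)
    se = float(values.std(ddof=1) / math.sqrt(reps)) if reps > 1 else 0.0
    return MCEstimate(float(values.mean()), se, reps, seed)


def mc_mean_snowflake_centers(n: int, reps: int, seed: int) -> MCEstimate:
    """Monte-Carlo estimate of ``E(X_n)``, the mean number of snowflake
    centres in a uniform binary tree on ``n`` leaves.

    The exact value is ``|S(n)|/B(n)`` from :mod:`.enumeration`; below 12
    leaves no snowflake fits and the estimate is exactly 0.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if n < 12:
        return MCEstimate(0.0, 0.0, reps, seed)
    vals = np.empty(reps)
    for i, rng in enumerate(_child_rngs(seed, reps)):
        vals[i] = count_snowflake_centers(sample_uniform_leaf_labelled(n, 2, rng))
    return _summarise(vals, seed)


def mc_second_moment_snowflake_centers(n: int, reps: int, seed: int) -> MCEstimate:
    """Monte-Carlo estimate of ``E(X_n^2)``.

    No closed form exists: the distance-separated part of the second moment
    is ``W(n)/B(n)`` and the near-pair remainder is only bounded (O(n) per
    tree), so this estimate is checked against a sanity envelope, not an
    equality."""
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if n < 12:
        return MCEstimate(0.0, 0.0, reps, seed)
    vals = np.empty(reps)
    for i, rng in enumerate(_child_rngs(seed, reps)):
        vals[i] = count_snowflake_centers(sample_uniform_leaf_labelled(n, 2, rng)) ** 2
    return _summarise(vals, seed)


def mc_zero_probability(n: int, reps: int, seed: int) -> MCEstimate:
    """Monte-Carlo estimate of ``P(X_n = 0)`` — the probability that a
    uniform binary tree on ``n`` leaves contains no snowflake.

    Exactly 1 below 12 leaves; tends to 0 as ``n`` grows, and its limit is
    in any case at most ``1 - 2^-7``."""
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if n < 12:
        return MCEstimate(1.0, 0.0, reps, seed)
    vals = np.empty(reps)
    for i, rng in enumerate(_child_rngs(seed, reps)):
        vals[i] = float(
            count_snowflake_centers(sample_uniform_leaf_labelled(n, 2, rng)) == 0
        )
    return _summarise(vals, seed)


_SNOWFLAKE_CODE = None


def _is_snowflake(tau: PatternTree) -> bool:
    global _SNOWFLAKE_CODE
    if _SNOWFLAKE_CODE is None:
        _SNOWFLAKE_CODE = snowflake_pattern().shape_code()
    return tau.n_vertices == 22 and tau.shape_code() == _SNOWFLAKE_CODE


def mc_pattern_curve(
    model: str,
    tau: PatternTree,
    n_grid: Sequence[int],
    d: int = 2,
    reps: int = 500,
    seed: int = 0,
) -> CurveResult:
    """Empirical occurrence frequency of ``tau`` along a leaf-count grid.

    ``model`` is ``"uniform"`` (uniform leaf-labelled d-ary trees) or
    ``"yule"`` (Yule–Harding, binary only).  If the pattern is not
    realizable for the model's offspring law the occurrence probability is
    exactly 0 for every ``n`` (the impossible side of the dichotomy): the
    curve is returned as zeros with ``short_circuit=True`` and no sampling
    is done.  For the snowflake on binary trees the linear-time
    central-vertex criterion is used instead of the generic embedding
    engine; the two are equivalent and that equivalence is tested
    separately.
    """
    model = {"uniform-dary": "uniform", "uniform": "uniform", "yule": "yule"}[model]
    if model == "yule" and d != 2:
        raise ValueError("the Yule–Harding model is binary (d=2)")
    n_grid = tuple(int(n) for n in n_grid)
    X = OffspringDistribution.dary(d)
    if not is_realizable(tau, X):
        ests = [MCEstimate(0.0, 0.0, reps, seed) for _ in n_grid]
        return CurveResult(model, repr(tau), d, n_grid, ests, short_circuit=True)
    fast_snowflake = d == 2 and _is_snowflake(tau)

    ests = []
    for gi, n in enumerate(n_grid):
        vals = np.empty(reps)
        # one independent child stream per (grid point, replicate)
        rngs = _child_rngs(seed + 100_003 * gi, reps)
        for i, rng in enumerate(rngs):
            if model == "uniform":
                T = sample_uniform_leaf_labelled(n, d, rng)
            else:
                T = sample_yule_harding(n, rng)
            if fast_snowflake:
                vals[i] = float(count_snowflake_centers(T) > 0)
            else:
                vals[i] = float(occurs(T, tau))
        ests.append(_summarise(vals, seed))
    return CurveResult(model, repr(tau), d, n_grid, ests)


def ball_tv_distance(
    X: OffspringDistribution,
    n_vertices: int,
    radius: int,
    reps: int,
    seed: int,
) -> float:
    """Empirical total-variation distance between the radius-``radius`` ball
    of a size-conditioned GW tree with ``n_vertices`` vertices and the same
    ball of the Kesten tree of ``X``.

    Both laws are estimated from ``reps`` draws via the ordered ball codes;
    the TV is computed on the union of observed supports, which biases it
    slightly downward — hence the radius should stay small (<= 3) so the
    ball space is well covered.  Local convergence of the conditioned trees
    to the Kesten tree drives this distance to 0 as ``n`` grows.
    """
    if radius == 0:
        return 0.0
    if radius > 3:
        raise ValueError("radius is capped at 3 (ball space grows too fast)")
    from collections import Counter

    cond: "Counter[Tuple[int, ...]]" = Counter()
    kest: "Counter[Tuple[int, ...]]" = Counter()
    for rng in _child_rngs(seed, reps):
        t = sample_conditioned_gw(X, n_vertices, rng)
        cond[t.ball(radius).out_degrees] += 1
    for rng in _child_rngs(seed + 1_000_003, reps):
        kb = sample_kesten_ball(X, radius, rng)
        kest[kb.tree.out_degrees] += 1
    support = set(cond) | set(kest)
    return 0.5 * sum(
        abs(cond[c] / reps - kest[c] / reps) for c in support
    )


def yule_split_test(n: int, reps: int, seed: int) -> Tuple[float, float]:
    """Chi-square goodness-of-fit of the Yule–Harding root split.

    For the rooted Yule–Harding tree on ``n`` leaves, the leaf count of one
    root subtree is uniform on ``{1, ..., n-1}``; returns the chi-square
    statistic and p-value of the observed counts against that uniform law.
    """
    if n < 3:
        raise ValueError("the root-split law needs n >= 3")
    counts = np.zeros(n - 1, dtype=np.int64)
    for rng in _child_rngs(seed, reps):
        t = sample_yule_harding(n, rng, keep_root=True)
        sizes = t.subtree_sizes()
        first_child = t.children_lists()[0][0]
        # leaves in the first root subtree: vertices in its preorder span
        span = t.out_degrees[first_child : first_child + sizes[first_child]]
        n1 = sum(1 for o in span if o == 0)
        counts[n1 - 1] += 1
    chi2, p = stats.chisquare(counts)
    return float(chi2), float(p)
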