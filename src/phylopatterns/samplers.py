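"""Random tree generators.

* :func:`sample_gw` — unconditioned Galton–Watson tree (preorder generation).
* :func:`sample_conditioned_gw` — GW tree conditioned on its total vertex
  count, sampled *exactly* by the cycle lemma: a conditioned i.i.d.
  out-degree sequence is exchangeable, and exactly one of its cyclic
  rotations is a valid preorder (Lukasiewicz) word; rotating to it yields
  the size-conditioned GW law in linear time.  For the d-ary offspring law
  ``X = d * Bernoulli(1/d)`` the number of internal vertices is
  deterministic, so no rejection at all is needed and the output is uniform
  over ordered d-ary trees with ``n`` vertices.
* :func:`sample_uniform_leaf_labelled` — exactly uniform unrooted
  leaf-labelled d-ary tree: a uniform ordered d-ary tree with ``n - 1``
  leaves, a leaf grafted to its root, a uniform leaf labelling, then the
  ordering and rooting discarded.
* :func:`sample_yule_harding` — the Yule–Harding model: starting from the
  two-leaf tree, repeatedly attach the next leaf to a uniformly chosen
  pendant edge (topological midpoint subdivision).
* :func:`sample_kesten_ball` — the radius-k ball of Kesten's size-biased
  tree: a spine of vertices each carrying ``X* - 1`` independent GW(X)
  subtrees (depth-truncated so the ball is exact in distribution), where
  ``X*`` is the size-biased offspring law.

All samplers take an explicit ``numpy.random.Generator``; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .trees import (
    LeafLabelledTree,
    RootedOrderedTree,
    ValidationError,
    graft_root_leaf_and_label,
)

__all__ = [
    "OffspringDistribution",
    "size_biased",
    "TruncatedTreeError",
    "sample_gw",
    "sample_conditioned_gw",
    "sample_conditioned_gw_rejection",
    "sample_uniform_leaf_labelled",
    "sample_yule_harding",
    "KestenBall",
    "sample_kesten_ball",
    "sample_spine_walk",
    "gw_probability",
]


class TruncatedTreeError(RuntimeError):
    """A Galton–Watson realisation exceeded the vertex budget."""


# ---------------------------------------------------------------------------
# Offspring distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OffspringDistribution:
    """A finite-support offspring law with exact rational probabilities.

    Moments (mean, second moment) are computed exactly with
    :class:`fractions.Fraction`; only the sampling path converts the
    probabilities to floats.
    """

    support: Tuple[int, ...]
    probabilities: Tuple[Fraction, ...]

    def __post_init__(self):
        supp = tuple(int(s) for s in self.support)
        probs = tuple(Fraction(p) for p in self.probabilities)
        if len(supp) != len(probs) or not supp:
            raise ValueError("support and probabilities must align and be non-empty")
        if any(s < 0 for s in supp):
            raise ValueError("offspring values must be non-negative")
        if len(set(supp)) != len(supp):
            raise ValueError("support values must be distinct")
        if any(p <= 0 for p in probs):
            raise ValueError("probabilities must be positive")
        if sum(probs) != 1:
            raise ValueError("probabilities must sum to 1 exactly")
        order = sorted(range(len(supp)), key=lambda i: supp[i])
        object.__setattr__(self, "support", tuple(supp[i] for i in order))
        object.__setattr__(self, "probabilities", tuple(probs[i] for i in order))

    @classmethod
    def from_dict(cls, law: Dict[int, Union[int, Fraction, str]]):
        return cls(tuple(law.keys()), tuple(Fraction(p) for p in law.values()))

    @classmethod
    def dary(cls, d: int) -> "OffspringDistribution":
        """``X = d * Bernoulli(1/d)``: the critical law whose size-conditioned
        GW tree is uniform over ordered d-ary trees."""
        if d < 2:
            raise ValueError("requires d >= 2")
        return cls((0, d), (Fraction(d - 1, d), Fraction(1, d)))

    def prob(self, k: int) -> Fraction:
        try:
            return self.probabilities[self.support.index(k)]
        except ValueError:
            return Fraction(0)

    def mean(self) -> Fraction:
        return sum(s * p for s, p in zip(self.support, self.probabilities))

    def second_moment(self) -> Fraction:
        return sum(s * s * p for s, p in zip(self.support, self.probabilities))

    def variance(self) -> Fraction:
        return self.second_moment() - self.mean() ** 2

    @property
    def is_critical(self) -> bool:
        return self.mean() == 1

    @property
    def p_zero(self) -> Fraction:
        return self.prob(0)

    def _float_probs(self) -> np.ndarray:
        return np.array([float(p) for p in self.probabilities])

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        """Draw from the law (floats enter only here)."""
        vals = np.asarray(self.support)
        idx = rng.choice(len(vals), size=size, p=self._float_probs())
        return vals[idx]


def size_biased(X: OffspringDistribution) -> OffspringDistribution:
    """The size-biased law ``P(X* = k) = k P(X = k) / E(X)`` (exact rationals).

    ``X* >= 1`` always; for ``X = d * Bernoulli(1/d)`` it is the point mass
    at ``d``.
    """
    mean = X.mean()
    if mean <= 0:
        raise ValueError("size-biasing requires a positive mean")
    supp = [s for s in X.support if s > 0]
    probs = [s * X.prob(s) / mean for s in supp]
    return OffspringDistribution(tuple(supp), tuple(probs))


def gw_probability(tree: RootedOrderedTree, X: OffspringDistribution) -> Fraction:
    """``P(GW(X) = tree) = prod_v P(X = outdeg(v))`` as an exact rational."""
    p = Fraction(1)
    for o in tree.out_degrees:
        p *= X.prob(o)
        if p == 0:
            return Fraction(0)
    return p


# ---------------------------------------------------------------------------
# Galton–Watson samplers
# ---------------------------------------------------------------------------


def sample_gw(
    X: OffspringDistribution,
    rng: np.random.Generator,
    max_vertices: int = 10**6,
) -> RootedOrderedTree:
    """An unconditioned GW(X) realisation (preorder generation).

    Raises :class:`TruncatedTreeError` when the tree exceeds ``max_vertices``
    — critical GW trees are almost surely finite but heavy-tailed, so the
    truncation signal is distinct from a successful draw.
    """
    if max_vertices < 1:
        raise ValueError("max_vertices must be >= 1")
    out: List[int] = []
    open_slots = 1
    buffer: List[int] = []
    while open_slots > 0:
        if not buffer:
            buffer = list(X.sample(rng, size=64))
        o = int(buffer.pop())
        out.append(o)
        open_slots += o - 1
        if len(out) > max_vertices:
            raise TruncatedTreeError(
                f"GW realisation exceeded {max_vertices} vertices"
            )
    return RootedOrderedTree(out, validate=False)


def _dary_form(X: OffspringDistribution) -> Optional[int]:
    """Return d if the support is {0, d} (or {0}/{d} degenerately), else None."""
    nz = [s for s in X.support if s > 0]
    if len(nz) == 1 and set(X.support) <= {0, nz[0]}:
        return nz[0]
    return None


def _cycle_lemma_rotate(seq: np.ndarray) -> np.ndarray:
    """Rotate an out-degree sequence with sum n-1 to its unique valid
    preorder word (start right after the first minimum of the walk)."""
    steps = seq - 1
    walk = np.cumsum(steps)
    m = int(np.argmin(walk))
    if m == len(seq) - 1:
        return seq
    return np.concatenate([seq[m + 1 :], seq[: m + 1]])


def sample_conditioned_gw(
    X: OffspringDistribution,
    n_vertices: int,
    rng: np.random.Generator,
    max_tries: int = 200_000,
) -> RootedOrderedTree:
    """A GW(X) tree conditioned to have exactly ``n_vertices`` vertices,
    sampled exactly via the cycle lemma.

    For ``X = d * Bernoulli(1/d)`` the out-degree multiset is deterministic
    (``(n-1)/d`` internal vertices) and the result is uniform over ordered
    d-ary trees with ``n_vertices`` vertices; ``n_vertices`` must satisfy
    ``n ≡ 1 (mod d)``.  For other laws the i.i.d. out-degree sequence is
    drawn conditioned on its sum by rejection before rotating.
    """
    n = int(n_vertices)
    if n < 1:
        raise ValueError("n_vertices must be >= 1")
    if n == 1:
        if X.prob(0) == 0:
            raise ValueError("n_vertices=1 impossible: P(X = 0) = 0")
        return RootedOrderedTree((0,), validate=False)
    d = _dary_form(X)
    if d is not None:
        if (n - 1) % d != 0:
            raise ValueError(
                f"impossible size for the {d}-ary offspring law: "
                f"n_vertices must satisfy n ≡ 1 (mod {d}), got n = {n}"
            )
        if X.prob(0) == 0 or X.prob(d) == 0:
            raise ValueError("degenerate law cannot produce trees of this size")
        i = (n - 1) // d
        seq = np.concatenate([np.full(i, d, dtype=np.int64), np.zeros(n - i, dtype=np.int64)])
        rng.shuffle(seq)
    else:
        target = n - 1
        seq = None
        for _ in range(max_tries):
            cand = X.sample(rng, size=n).astype(np.int64)
            if int(cand.sum()) == target:
                seq = cand
                break
        if seq is None:
            raise ValueError(
                f"could not realise a GW tree with {n} vertices after "
                f"{max_tries} tries; the size may violate a support "
                "congruence or be extremely unlikely"
            )
    word = _cycle_lemma_rotate(seq)
    return RootedOrderedTree(word.tolist(), validate=False)


def sample_conditioned_gw_rejection(
    X: OffspringDistribution,
    n_vertices: int,
    rng: np.random.Generator,
    max_tries: int = 1_000_000,
) -> RootedOrderedTree:
    """Size-conditioned GW tree by plain rejection on whole realisations.

    Exact but slow; kept as an independent oracle for the cycle-lemma sampler.
    """
    for _ in range(max_tries):
        try:
            t = sample_gw(X, rng, max_vertices=n_vertices)
        except TruncatedTreeError:
            continue
        if t.n_vertices == n_vertices:
            return t
    raise ValueError(f"no tree of size {n_vertices} found in {max_tries} tries")


def sample_uniform_leaf_labelled(
    n_leaves: int, d: int = 2, rng: Optional[np.random.Generator] = None
) -> LeafLabelledTree:
    """An exactly uniform unrooted d-ary tree with ``n_leaves`` labelled leaves.

    Pipeline: uniform ordered d-ary tree with ``n - 1`` leaves (size-
    conditioned GW), graft a leaf at the root, label uniformly, unroot.  For
    ``d = 2`` the law is uniform over all ``(2n - 5)!!`` binary phylogenetic
    trees.
    """
    if rng is None:
        raise ValueError("an rng is required")
    n = int(n_leaves)
    if n < 2:
        raise ValueError("need n_leaves >= 2")
    if n == 2:
        return LeafLabelledTree({0: [1], 1: [0]}, {0: 1, 1: 2}, d=d)
    if (n - 2) % (d - 1) != 0:
        raise ValueError(
            f"no {d}-ary tree has {n} leaves: need (n - 2) divisible by {d - 1}"
        )
    k = (n - 2) // (d - 1)  # internal vertices of the ordered tree
    m = d * k + 1  # its vertex count; it has n - 1 leaves
    t = sample_conditioned_gw(OffspringDistribution.dary(d), m, rng)
    return graft_root_leaf_and_label(t, labels=None, rng=rng, d=d)


# ---------------------------------------------------------------------------
# Yule–Harding
# ---------------------------------------------------------------------------


def sample_yule_harding(
    n_leaves: int,
    rng: np.random.Generator,
    keep_root: bool = False,
) -> Union[LeafLabelledTree, RootedOrderedTree]:
    """A Yule–Harding tree on ``n_leaves`` leaves.

    Construction: start with the two-leaf tree; to add leaf ``i``, pick a
    pendant edge uniformly at random and attach leaf ``i`` at its subdivided
    midpoint (purely topological).  This is the shape distribution of a wide
    class of birth–death models.

    With ``keep_root=True`` the rooted tree is returned (as a
    :class:`RootedOrderedTree`, sibling order randomised, leaf labels
    dropped); otherwise the degree-2 root is suppressed and the unrooted
    :class:`LeafLabelledTree` is returned with a uniformly random leaf
    labelling, making the law exchangeable over labels (the shape carries
    the Yule–Harding distribution; labels are uninformative).
    """
    n = int(n_leaves)
    if n < 2:
        raise ValueError("need n_leaves >= 2")
    children: Dict[int, List[int]] = {0: [1, 2]}
    labels: Dict[int, int] = {1: 1, 2: 2}
    leaves: List[int] = [1, 2]
    nxt = 3
    coin = rng.random(size=max(n - 2, 1)) < 0.5
    for step, lbl in enumerate(range(3, n + 1)):
        j = int(rng.integers(len(leaves)))
        u = leaves[j]
        a, b = nxt, nxt + 1  # a keeps u's label, b is the new leaf
        nxt += 2
        children[u] = [a, b] if coin[step] else [b, a]
        labels[a] = labels.pop(u)
        labels[b] = lbl
        leaves[j] = a
        leaves.append(b)

    if keep_root:
        seq: List[int] = []
        stack = [0]
        while stack:
            v = stack.pop()
            cs = children.get(v, [])
            seq.append(len(cs))
            stack.extend(reversed(cs))
        return RootedOrderedTree(seq, validate=False)

    if n == 2:
        return LeafLabelledTree({0: [1], 1: [0]}, {0: 1, 1: 2}, d=2)
    adj: Dict[int, List[int]] = {}
    for v, cs in children.items():
        for c in cs:
            if v == 0:
                continue
            adj.setdefault(v, []).append(c)
            adj.setdefault(c, []).append(v)
    a, b = children[0]
    adj.setdefault(a, []).append(b)
    adj.setdefault(b, []).append(a)
    for leaf in leaves:
        adj.setdefault(leaf, [])
    perm = rng.permutation(n) + 1
    labels = {v: int(perm[lbl - 1]) for v, lbl in labels.items()}
    return LeafLabelledTree(adj, labels, d=2)


# ---------------------------------------------------------------------------
# Kesten's size-biased tree, truncated to a ball
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KestenBall:
    """The radius-k ball of a Kesten tree, with its marked spine.

    ``spine`` lists the Ulam–Harris addresses of the spine vertices
    ``v_1 ... v_{k+1}`` (root first); ``spine_out_edges`` holds the running
    counts ``S_j = sum_{i<=j} (outdeg(v_i) - 1)`` for ``j = 1..k`` — the
    number of off-spine edges emitted within distance ``j`` of the root.
    """

    tree: RootedOrderedTree
    spine: Tuple[Tuple[int, ...], ...]
    radius: int
    spine_out_edges: Tuple[int, ...]


def _gw_depth_truncated(
    X: OffspringDistribution, budget: int, rng: np.random.Generator, out: List[int]
) -> None:
    if budget == 0:
        out.append(0)
        return
    o = int(X.sample(rng))
    out.append(o)
    for _ in range(o):
        _gw_depth_truncated(X, budget - 1, rng, out)


def sample_kesten_ball(
    X: OffspringDistribution, radius: int, rng: np.random.Generator
) -> KestenBall:
    """Sample ``[T*]_k``, the radius-``k`` ball of the Kesten tree of ``X``.

    Requires ``X`` critical (mean exactly 1) with ``P(X = 0) > 0``.  Each
    spine vertex at depth ``< k`` draws ``X*`` children, one of which (at a
    uniformly random position) continues the spine; the others root
    independent GW(X) trees truncated at their remaining depth budget, so
    the returned ball is exact in distribution.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if not X.is_critical:
        raise ValueError("Kesten tree requires a critical offspring law (mean 1)")
    if X.p_zero == 0:
        raise ValueError("Kesten tree requires P(X = 0) > 0")
    Xstar = size_biased(X)

    seq: List[int] = []
    spine_addrs: List[Tuple[int, ...]] = []
    spine_degs: List[int] = []

    def build_spine(depth: int, addr: Tuple[int, ...]) -> None:
        spine_addrs.append(addr)
        if depth == radius:
            seq.append(0)
            return
        x = int(Xstar.sample(rng))
        spine_degs.append(x)
        pos = int(rng.integers(x))
        seq.append(x)
        for i in range(x):
            if i == pos:
                build_spine(depth + 1, addr + (i + 1,))
            else:
                _gw_depth_truncated(X, radius - depth - 1, rng, seq)

    build_spine(0, ())
    tree = RootedOrderedTree(seq, validate=False)
    s_running = 0
    s_list: List[int] = []
    for x in spine_degs:
        s_running += x - 1
        s_list.append(s_running)
    return KestenBall(
        tree=tree,
        spine=tuple(spine_addrs),
        radius=radius,
        spine_out_edges=tuple(s_list),
    )


def sample_spine_walk(
    X: OffspringDistribution, k: int, rng: np.random.Generator
) -> List[int]:
    """The spine walk ``(S_1, ..., S_k)`` of a Kesten tree, sampled directly
    from ``X* - 1`` increments (no subtrees are built)."""
    if not X.is_critical:
        raise ValueError("requires a critical offspring law")
    incs = size_biased(X).sample(rng, size=k) - 1
    return list(np.cumsum(incs))
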