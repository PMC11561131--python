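"""Core tree data structures and exhaustive small-tree generators.

Three kinds of trees are used throughout the package:

* :class:`LeafLabelledTree` — an unrooted *d*-ary phylogenetic tree: every
  vertex has degree 1 (a leaf) or ``d + 1`` (an internal vertex), and the
  leaves carry the labels ``1..n``.  For ``d = 2`` these are the classical
  binary phylogenetic trees.
* :class:`RootedOrderedTree` — a rooted plane tree whose vertices are
  addressed by Ulam–Harris words (the root is the empty word, the k-th child
  of ``w`` is ``w + (k,)``).  Galton–Watson realisations, size-conditioned
  trees and balls around the root all live here.
* :class:`PatternTree` — a finite unlabelled tree whose vertices are
  partitioned into *internal* vertices (degree >= 2, whose degree must be
  matched exactly by an embedding) and *free leaves* (degree <= 1, which
  stand for arbitrary hanging subtrees).  Defined in :mod:`.patterns`.

The plane trees are stored as their preorder out-degree sequence (the
Lukasiewicz word), which makes sampling, truncation and serialisation cheap.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

Adjacency = Dict[int, List[int]]

__all__ = [
    "ValidationError",
    "RootedOrderedTree",
    "LeafLabelledTree",
    "graft_root_leaf_and_label",
    "enumerate_all_unrooted",
    "enumerate_ordered_trees",
    "enumerate_free_trees",
    "canonical_code",
    "free_tree_code",
]


class ValidationError(ValueError):
    """A structure violates one of the tree-class invariants."""


def _double_factorial(m: int) -> int:
    out = 1
    while m > 1:
        out *= m
        m -= 2
    return out


# ---------------------------------------------------------------------------
# Rooted ordered (plane) trees
# ---------------------------------------------------------------------------


class RootedOrderedTree:
    """A rooted tree with ordered children.

    Internally the tree is its preorder sequence of out-degrees.  A sequence
    ``(o_1, ..., o_m)`` encodes a tree iff the walk with steps ``o_i - 1``
    stays non-negative before the last step and ends at ``-1``; there is then
    exactly one tree with that preorder sequence.
    """

    __slots__ = ("out_degrees",)

    def __init__(self, out_degrees: Sequence[int], validate: bool = True):
        self.out_degrees: Tuple[int, ...] = tuple(int(o) for o in out_degrees)
        if validate:
            self._validate()

    def _validate(self) -> None:
        seq = self.out_degrees
        if not seq:
            raise ValidationError("a rooted tree has at least one vertex")
        s = 0
        last = len(seq) - 1
        for i, o in enumerate(seq):
            if o < 0:
                raise ValidationError(f"negative out-degree at preorder index {i}")
            s += o - 1
            if s < 0 and i < last:
                raise ValidationError(
                    f"out-degree sequence closes prematurely at preorder index {i}"
                )
        if s != -1:
            raise ValidationError("out-degree sequence leaves unfilled child slots")

    # -- basic shape ------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.out_degrees)

    @property
    def n_leaves(self) -> int:
        return sum(1 for o in self.out_degrees if o == 0)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RootedOrderedTree)
            and self.out_degrees == other.out_degrees
        )

    def __hash__(self) -> int:
        return hash(self.out_degrees)

    def __repr__(self) -> str:
        return f"RootedOrderedTree(n_vertices={self.n_vertices})"

    # -- derived structure -------------------------------------------------

    def children_lists(self) -> List[List[int]]:
        """Children of each vertex, as preorder indices."""
        seq = self.out_degrees
        ch: List[List[int]] = [[] for _ in seq]
        stack: List[List[int]] = []  # [vertex, remaining child slots]
        for i, o in enumerate(seq):
            if stack:
                ch[stack[-1][0]].append(i)
                stack[-1][1] -= 1
            if o > 0:
                stack.append([i, o])
            else:
                while stack and stack[-1][1] == 0:
                    stack.pop()
        return ch

    def depths(self) -> List[int]:
        """Edge-distance of each vertex (preorder) from the root."""
        seq = self.out_degrees
        out: List[int] = []
        stack: List[int] = []  # remaining child slots per open ancestor
        for o in seq:
            out.append(len(stack))
            if stack:
                stack[-1] -= 1
            if o > 0:
                stack.append(o)
            else:
                while stack and stack[-1] == 0:
                    stack.pop()
        return out

    def height(self) -> int:
        return max(self.depths())

    def addresses(self) -> List[Tuple[int, ...]]:
        """Ulam–Harris address of each vertex, in preorder (1-based words)."""
        seq = self.out_degrees
        out: List[Tuple[int, ...]] = []
        # stack entries: [address, next child index, remaining slots]
        stack: List[list] = []
        for o in seq:
            if stack:
                parent_addr, idx, _ = stack[-1]
                addr = parent_addr + (idx,)
                stack[-1][1] += 1
                stack[-1][2] -= 1
            else:
                addr = ()
            out.append(addr)
            if o > 0:
                stack.append([addr, 1, o])
            else:
                while stack and stack[-1][2] == 0:
                    stack.pop()
        return out

    def out_degree_map(self) -> Dict[Tuple[int, ...], int]:
        return dict(zip(self.addresses(), self.out_degrees))

    # -- operations --------------------------------------------------------

    def ball(self, k: int) -> "RootedOrderedTree":
        """The ball ``[T]_k``: the induced subtree of all vertices at depth <= k.

        Vertices exactly at depth ``k`` keep their position but lose their
        children, so the result is again a plane tree.
        """
        if k < 0:
            raise ValueError("radius must be >= 0")
        res: List[int] = []
        stack: List[int] = []
        for o in self.out_degrees:
            depth = len(stack)
            if depth <= k:
                res.append(o if depth < k else 0)
            if stack:
                stack[-1] -= 1
            if o > 0:
                stack.append(o)
            else:
                while stack and stack[-1] == 0:
                    stack.pop()
        return RootedOrderedTree(res, validate=False)

    def subtree_sizes(self) -> List[int]:
        """Number of vertices in the subtree rooted at each preorder index."""
        seq = self.out_degrees
        sizes = [1] * len(seq)
        ch = self.children_lists()
        for i in range(len(seq) - 1, -1, -1):
            for c in ch[i]:
                sizes[i] += sizes[c]
        return sizes

    def to_adjacency(self) -> Adjacency:
        """Underlying unrooted graph (vertex ids = preorder indices)."""
        adj: Adjacency = {i: [] for i in range(self.n_vertices)}
        for v, cs in enumerate(self.children_lists()):
            for c in cs:
                adj[v].append(c)
                adj[c].append(v)
        return adj

    def ordered_code(self) -> Tuple[int, ...]:
        """Canonical code respecting child order (the preorder sequence itself)."""
        return self.out_degrees

    def unordered_code(self) -> str:
        """Canonical code of the rooted shape, ignoring child order."""
        ch = self.children_lists()

        def code(v: int) -> str:
            if not ch[v]:
                return "()"
            return "(" + "".join(sorted(code(c) for c in ch[v])) + ")"

        return code(0)

    @classmethod
    def from_nested(cls, nested) -> "RootedOrderedTree":
        """Build from nested sequences: a leaf is ``()``, an internal vertex a
        tuple/list of its children, e.g. ``((), ((), ()))``."""
        seq: List[int] = []

        def walk(node) -> None:
            seq.append(len(node))
            for child in node:
                walk(child)

        walk(nested)
        return cls(seq)


# ---------------------------------------------------------------------------
# Unrooted leaf-labelled d-ary trees
# ---------------------------------------------------------------------------


class LeafLabelledTree:
    """Unrooted *d*-ary tree with leaves labelled ``1..n``.

    ``adjacency`` maps vertex ids (arbitrary hashable ints) to neighbour
    lists; ``leaf_labels`` maps each degree-1 vertex to its label.
    """

    __slots__ = ("adjacency", "leaf_labels", "d")

    def __init__(
        self,
        adjacency: Adjacency,
        leaf_labels: Dict[int, int],
        d: int = 2,
        validate: bool = True,
    ):
        self.adjacency: Adjacency = {v: list(ns) for v, ns in adjacency.items()}
        self.leaf_labels: Dict[int, int] = dict(leaf_labels)
        self.d = int(d)
        if validate:
            self._validate()

    def _validate(self) -> None:
        adj = self.adjacency
        d = self.d
        if d < 2:
            raise ValidationError("arity d must be >= 2")
        n = len(self.leaf_labels)
        if n < 2:
            raise ValidationError("a leaf-labelled tree needs at least 2 leaves")
        if sorted(self.leaf_labels.values()) != list(range(1, n + 1)):
            raise ValidationError(f"leaf labels must be exactly 1..{n} with no repeats")
        n_edges = sum(len(ns) for ns in adj.values())
        if n_edges % 2:
            raise ValidationError("adjacency is not symmetric")
        n_edges //= 2
        if n_edges != len(adj) - 1:
            raise ValidationError("edge count does not match a tree")
        for v, ns in adj.items():
            if len(set(ns)) != len(ns):
                raise ValidationError(f"repeated edge at vertex {v}")
            deg = len(ns)
            if deg == 1 or (deg == 0 and len(adj) == 1):
                if v not in self.leaf_labels:
                    raise ValidationError(f"degree-1 vertex {v} carries no leaf label")
            elif deg == d + 1:
                if v in self.leaf_labels:
                    raise ValidationError(f"internal vertex {v} carries a leaf label")
            else:
                raise ValidationError(
                    f"vertex {v} has degree {deg}; expected 1 or {d + 1}"
                )
        # connectivity (acyclicity follows from edge count)
        seen = set()
        start = next(iter(adj))
        stack = [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(w for w in adj[v] if w not in seen)
        if len(seen) != len(adj):
            raise ValidationError("tree is not connected")

    # -- basic shape ------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_vertices(self) -> int:
        return len(self.adjacency)

    def degree(self, v: int) -> int:
        return len(self.adjacency[v])

    @property
    def leaves(self) -> List[int]:
        return list(self.leaf_labels)

    @property
    def internal_vertices(self) -> List[int]:
        return [v for v in self.adjacency if v not in self.leaf_labels]

    def label_to_vertex(self) -> Dict[int, int]:
        return {lbl: v for v, lbl in self.leaf_labels.items()}

    def __repr__(self) -> str:
        return f"LeafLabelledTree(n_leaves={self.n_leaves}, d={self.d})"

    # -- operations --------------------------------------------------------

    def nearest_leaf_distances(self) -> Dict[int, int]:
        """Edge-distance from every vertex to its nearest leaf (multi-source BFS)."""
        from collections import deque

        dist = {v: 0 for v in self.leaf_labels}
        queue = deque(self.leaf_labels)
        while queue:
            v = queue.popleft()
            for w in self.adjacency[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        return dist

    def canonical_code(self) -> str:
        """Label-respecting canonical code.

        The tree is rooted at the leaf labelled 1 (a canonical choice), and the
        code is built recursively with sorted child codes.  Two trees get equal
        codes iff they are isomorphic as leaf-labelled trees.
        """
        adj = self.adjacency
        labels = self.leaf_labels
        root = self.label_to_vertex()[1]

        def code(v: int, parent: Optional[int]) -> str:
            parts = sorted(code(w, v) for w in adj[v] if w != parent)
            base = str(labels[v]) if v in labels else ""
            if parts:
                return base + "(" + ",".join(parts) + ")"
            return base

        return code(root, None)


def canonical_code(tree) -> str:
    """Canonical code dispatching on the tree type.

    * :class:`LeafLabelledTree` — label-respecting unrooted code;
    * :class:`RootedOrderedTree` — unordered rooted-shape code (use
      :meth:`RootedOrderedTree.ordered_code` for the order-respecting variant).
    """
    if isinstance(tree, LeafLabelledTree):
        return tree.canonical_code()
    if isinstance(tree, RootedOrderedTree):
        return tree.unordered_code()
    raise TypeError(f"unsupported tree type: {type(tree)!r}")


# ---------------------------------------------------------------------------
# Grafting: ordered d-ary tree  ->  unrooted leaf-labelled d-ary tree
# ---------------------------------------------------------------------------


def graft_root_leaf_and_label(
    t: RootedOrderedTree,
    labels: Optional[Sequence[int]] = None,
    rng=None,
    d: Optional[int] = None,
) -> LeafLabelledTree:
    """Attach a pendant leaf to the root of ``t``, label all leaves, unroot.

    ``t`` must be an ordered d-ary tree (out-degrees 0 or ``d``) with ``n - 1``
    leaves; the result is an unrooted d-ary tree on ``n`` labelled leaves.  The
    old root gains the new pendant edge and becomes internal of degree
    ``d + 1``.  Leaves of ``t`` receive ``labels[0:n-1]`` in preorder and the
    grafted leaf receives ``labels[n-1]``; with a uniformly random permutation
    (``labels=None`` and an ``rng``) the output of a uniform ordered tree is
    uniform over all leaf-labelled d-ary trees.
    """
    degs = set(t.out_degrees) - {0}
    if d is None:
        d = degs.pop() if len(degs) == 1 else 2
    if degs - {d}:
        raise ValidationError(f"tree is not {d}-ary: out-degrees {sorted(degs)}")
    n = t.n_leaves + 1
    if labels is None:
        if rng is None:
            raise ValueError("provide labels or an rng")
        labels = [int(x) for x in rng.permutation(n) + 1]
    labels = list(labels)
    if sorted(labels) != list(range(1, n + 1)):
        raise ValueError(f"labels must be a permutation of 1..{n}")

    m = t.n_vertices
    adj: Adjacency = {i: [] for i in range(m + 1)}
    for v, cs in enumerate(t.children_lists()):
        for c in cs:
            adj[v].append(c)
            adj[c].append(v)
    adj[0].append(m)  # grafted leaf
    adj[m].append(0)
    leaf_labels: Dict[int, int] = {}
    it = iter(labels)
    for i, o in enumerate(t.out_degrees):
        if o == 0:
            leaf_labels[i] = next(it)
    leaf_labels[m] = next(it)
    return LeafLabelledTree(adj, leaf_labels, d=d)


# ---------------------------------------------------------------------------
# Exhaustive generators (test oracles)
# ---------------------------------------------------------------------------

_ENUM_GUARD = 10**6


def enumerate_all_unrooted(
    n: int, d: int = 2, force: bool = False
) -> Iterator[LeafLabelledTree]:
    """Yield every leaf-labelled d-ary tree on ``n`` leaves exactly once.

    For ``d = 2`` the count is ``(2n - 5)!!`` and the generator proceeds by
    inserting leaf ``k`` into every edge of every tree on ``k - 1`` leaves
    (each tree arises exactly once because deleting the highest leaf is a
    left inverse).  For ``d > 2`` all ordered d-ary shapes and labellings are
    grafted and de-duplicated by canonical code — small ``n`` only.
    """
    if n < 2:
        raise ValueError("need n >= 2 leaves")
    if d == 2:
        if not force and _double_factorial(2 * n - 5) > _ENUM_GUARD:
            raise ValueError(
                f"B({n}) = (2n-5)!! exceeds {_ENUM_GUARD}; pass force=True to override"
            )
        yield from _enumerate_binary(n)
        return
    if (n - 2) % (d - 1) != 0 and n > 2:
        return
    if not force and n > d + 4:
        raise ValueError("exhaustive d-ary enumeration is limited to small n")
    seen = set()
    k_internal = 0 if n == 2 else (n - 2) // (d - 1)
    m = d * k_internal + 1
    for t in enumerate_ordered_trees(m, (0, d)):
        for perm in itertools.permutations(range(1, n + 1)):
            tree = graft_root_leaf_and_label(t, perm, d=d)
            code = tree.canonical_code()
            if code not in seen:
                seen.add(code)
                yield tree


def _enumerate_binary(n: int) -> Iterator[LeafLabelledTree]:
    # A tree is (edges, next fresh vertex id); leaves are vertices 1..n,
    # internal vertices get ids above n.
    def build(k: int):
        if k == 2:
            yield [(1, 2)], n + 1
            return
        for edges, nxt in build(k - 1):
            for i in range(len(edges)):
                u, v = edges[i]
                w = nxt
                new_edges = edges[:i] + edges[i + 1 :]
                new_edges += [(u, w), (w, v), (w, k)]
                yield new_edges, nxt + 1

    for edges, _ in build(n):
        adj: Adjacency = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        yield LeafLabelledTree(adj, {i: i for i in range(1, n + 1)}, d=2)


@lru_cache(maxsize=None)
def _ordered_trees_cached(
    n_vertices: int, out_degrees: Tuple[int, ...]
) -> Tuple[Tuple[int, ...], ...]:
    if n_vertices < 1:
        return ()
    if n_vertices == 1:
        return ((0,),) if 0 in out_degrees else ()
    res: List[Tuple[int, ...]] = []
    for k in out_degrees:
        if k < 1 or k > n_vertices - 1:
            continue

        def compositions(total: int, parts: int):
            if parts == 1:
                sub = _ordered_trees_cached(total, out_degrees)
                for s in sub:
                    yield (s,)
                return
            for first in range(1, total - parts + 2):
                subs = _ordered_trees_cached(first, out_degrees)
                if not subs:
                    continue
                for rest in compositions(total - first, parts - 1):
                    for s in subs:
                        yield (s,) + rest

        for combo in compositions(n_vertices - 1, k):
            seq: Tuple[int, ...] = (k,)
            for s in combo:
                seq = seq + s
            res.append(seq)
    return tuple(res)


def enumerate_ordered_trees(
    n_vertices: int, out_degrees: Iterable[int]
) -> List[RootedOrderedTree]:
    """All ordered trees with the given vertex count and allowed out-degrees."""
    degs = tuple(sorted(set(int(x) for x in out_degrees)))
    return [
        RootedOrderedTree(seq, validate=False)
        for seq in _ordered_trees_cached(n_vertices, degs)
    ]


# ---------------------------------------------------------------------------
# Free (unlabelled, unrooted) trees — used to build the pattern test grid
# ---------------------------------------------------------------------------


def _rooted_shape_code(adj: Adjacency, root: int) -> str:
    def code(v: int, parent: Optional[int]) -> str:
        parts = sorted(code(w, v) for w in adj[v] if w != parent)
        return "(" + "".join(parts) + ")"

    return code(root, None)


def tree_centroids(adj: Adjacency) -> List[int]:
    """The one or two centroids of a tree given as an adjacency dict."""
    m = len(adj)
    if m == 1:
        return list(adj)
    best: List[int] = []
    best_weight = m + 1
    sizes: Dict[int, int] = {}

    order: List[Tuple[int, Optional[int]]] = []
    stack: List[Tuple[int, Optional[int]]] = [(next(iter(adj)), None)]
    while stack:
        v, p = stack.pop()
        order.append((v, p))
        for w in adj[v]:
            if w != p:
                stack.append((w, v))
    for v, p in reversed(order):
        sizes[v] = 1 + sum(sizes[w] for w in adj[v] if w != p)
    for v, p in order:
        weight = max(
            [m - sizes[v]] + [sizes[w] for w in adj[v] if w != p] or [0]
        )
        if weight < best_weight:
            best_weight = weight
            best = [v]
        elif weight == best_weight:
            best.append(v)
    return best


def free_tree_code(adj: Adjacency) -> str:
    """Canonical code of an unlabelled unrooted tree (rooted at its centroid)."""
    return min(_rooted_shape_code(adj, c) for c in tree_centroids(adj))


def enumerate_free_trees(n_vertices: int) -> List[Adjacency]:
    """All unlabelled trees on ``n_vertices`` vertices, via Pruefer sequences
    de-duplicated by centroid canonical code.  Intended for small sizes."""
    m = n_vertices
    if m < 1:
        return []
    if m == 1:
        return [{0: []}]
    if m == 2:
        return [{0: [1], 1: [0]}]
    if m > 9:
        raise ValueError("free-tree enumeration is limited to <= 9 vertices")
    seen: Dict[str, Adjacency] = {}
    for seq in itertools.product(range(m), repeat=m - 2):
        adj = _pruefer_to_tree(seq, m)
        code = free_tree_code(adj)
        if code not in seen:
            seen[code] = adj
    return list(seen.values())


def _pruefer_to_tree(seq: Sequence[int], m: int) -> Adjacency:
    degree = [1] * m
    for v in seq:
        degree[v] += 1
    adj: Adjacency = {i: [] for i in range(m)}
    import heapq

    leaves = [v for v in range(m) if degree[v] == 1]
    heapq.heapify(leaves)
    for v in seq:
        u = heapq.heappop(leaves)
        adj[u].append(v)
        adj[v].append(u)
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    adj[u].append(v)
    adj[v].append(u)
    return adj
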