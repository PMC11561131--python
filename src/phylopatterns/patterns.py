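"""Pattern trees, degree-exact occurrence, and realizability.

A :class:`PatternTree` is a finite unlabelled tree whose vertices are either
*internal* (degree >= 2) or *free leaves* (degree <= 1).  A free leaf stands
for an arbitrary hanging rooted subtree on one or more leaves, so the
occurrence relation ``T ⊃ τ`` used here is **degree-exact**: an embedding
must map internal pattern vertices to host vertices of *equal* degree, with
every host neighbour covered by the image of a pattern neighbour; free
leaves are unconstrained.  Under this semantics a pattern occurs in a
size-conditioned Galton–Watson tree with positive probability iff it is
realizable for the offspring law, which is the dichotomy the occurrence
0–1 law rests on.  The plain (non-induced) subtree containment is available
separately as :func:`occurs_subgraph`.

The *snowflake* is the 22-vertex pattern with a central vertex, three
internal neighbours, six internal grand-neighbours and twelve free leaves.
A vertex of a binary tree is the centre of a snowflake iff its edge-distance
to every leaf is at least 3, which gives a linear-time detector
(:func:`snowflake_central_vertices`) cross-checked against the generic
embedding machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .samplers import OffspringDistribution
from .trees import (
    Adjacency,
    LeafLabelledTree,
    RootedOrderedTree,
    ValidationError,
    free_tree_code,
)

__all__ = [
    "PatternTree",
    "snowflake_pattern",
    "pattern_diameter",
    "occurs",
    "occurs_subgraph",
    "occurs_at",
    "find_embedding",
    "brute_force_occurs",
    "snowflake_central_vertices",
    "count_snowflake_centers",
    "snowflake_centers_by_embedding",
    "Realizability",
    "is_realizable",
]

Host = Union[LeafLabelledTree, RootedOrderedTree, Adjacency]


class PatternTree:
    """A finite tree with an internal / free-leaf vertex partition.

    Invariants: free leaves have degree <= 1; internal vertices have degree
    >= 2 — so the roles are forced by the degrees (a single isolated vertex
    is a free leaf).
    """

    __slots__ = ("adjacency", "free_leaves")

    def __init__(self, adjacency: Adjacency, free_leaves=None, validate: bool = True):
        self.adjacency: Adjacency = {v: list(ns) for v, ns in adjacency.items()}
        if free_leaves is None:
            free_leaves = {v for v, ns in self.adjacency.items() if len(ns) <= 1}
        self.free_leaves: Set[int] = set(free_leaves)
        if validate:
            self._validate()

    def _validate(self) -> None:
        adj = self.adjacency
        if not adj:
            raise ValidationError("empty pattern")
        n_edges = sum(len(ns) for ns in adj.values())
        if n_edges % 2 or n_edges // 2 != len(adj) - 1:
            raise ValidationError("pattern is not a tree")
        for v, ns in adj.items():
            deg = len(ns)
            if v in self.free_leaves:
                if deg > 1:
                    raise ValidationError(
                        f"free leaf {v} has degree {deg} (must be <= 1)"
                    )
            elif deg < 2:
                raise ValidationError(
                    f"vertex {v} has degree {deg} but is marked internal"
                )
        seen = set()
        stack = [next(iter(adj))]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(adj[v])
        if len(seen) != len(adj):
            raise ValidationError("pattern is not connected")

    @property
    def n_vertices(self) -> int:
        return len(self.adjacency)

    @property
    def internal_vertices(self) -> List[int]:
        return [v for v in self.adjacency if v not in self.free_leaves]

    def degree(self, v: int) -> int:
        return len(self.adjacency[v])

    def shape_code(self) -> str:
        return free_tree_code(self.adjacency)

    def __repr__(self) -> str:
        return (
            f"PatternTree(n_vertices={self.n_vertices}, "
            f"n_free_leaves={len(self.free_leaves)})"
        )

    @classmethod
    def from_newick(cls, text: str) -> "PatternTree":
        """Parse a pattern: leaves named ``_`` are free leaves; every other
        vertex is internal (and must therefore have degree >= 2)."""
        from . import newick as _nwk

        tree = _nwk._dendropy_parse(text, suppress_leaf_taxa=True)
        ids: Dict[object, int] = {}
        for i, node in enumerate(tree.preorder_node_iter()):
            ids[node] = i
        adj: Adjacency = {i: [] for i in ids.values()}
        free: Set[int] = set()
        for node, i in ids.items():
            for child in node.child_nodes():
                j = ids[child]
                adj[i].append(j)
                adj[j].append(i)
            if not node.child_nodes():
                name = _nwk._leaf_name(node)
                if name == "_":
                    free.add(i)
        return cls(adj, free)

    def to_newick(self) -> str:
        adj = self.adjacency
        internal = self.internal_vertices
        root = min(internal) if internal else min(adj)

        def sub(v: int, parent: Optional[int]) -> str:
            parts = sorted(sub(w, v) for w in adj[v] if w != parent)
            if not parts:
                return "_" if v in self.free_leaves else str(v)
            return "(" + ",".join(parts) + ")"

        return sub(root, None) + ";"


def snowflake_pattern() -> PatternTree:
    """The snowflake: centre 0 (degree 3), three internal neighbours, six
    internal grand-neighbours, twelve free leaves; 22 vertices, diameter 6."""
    adj: Adjacency = {0: []}
    free: Set[int] = set()
    nxt = 1
    for _ in range(3):
        a = nxt
        nxt += 1
        adj[0].append(a)
        adj[a] = [0]
        for _ in range(2):
            b = nxt
            nxt += 1
            adj[a].append(b)
            adj[b] = [a]
            for _ in range(2):
                c = nxt
                nxt += 1
                adj[b].append(c)
                adj[c] = [b]
                free.add(c)
    return PatternTree(adj, free)


def pattern_diameter(tau: PatternTree) -> int:
    """Maximal pairwise edge-distance (two BFS sweeps)."""
    adj = tau.adjacency

    def farthest(src: int) -> Tuple[int, int]:
        from collections import deque

        dist = {src: 0}
        q = deque([src])
        far, fd = src, 0
        while q:
            v = q.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    if dist[w] > fd:
                        far, fd = w, dist[w]
                    q.append(w)
        return far, fd

    a, _ = farthest(next(iter(adj)))
    _, diam = farthest(a)
    return diam


# ---------------------------------------------------------------------------
# Host helpers
# ---------------------------------------------------------------------------


def _host_adjacency(host: Host) -> Adjacency:
    if isinstance(host, LeafLabelledTree):
        return host.adjacency
    if isinstance(host, RootedOrderedTree):
        return host.to_adjacency()
    if isinstance(host, dict):
        return host
    raise TypeError(f"unsupported host type: {type(host)!r}")


def _bipartite_perfect_matching(n_left: int, adj_lists: List[List[int]]) -> Optional[List[int]]:
    """Perfect matching on a small bipartite graph; returns for each left
    vertex its matched right vertex, or None if no perfect matching exists.
    ``adj_lists[i]`` lists the right vertices available to left vertex i
    (candidates are tried in the given order, so ordering them makes the
    result deterministic)."""
    match_right: Dict[int, int] = {}

    def augment(i: int, visited: Set[int]) -> bool:
        for j in adj_lists[i]:
            if j in visited:
                continue
            visited.add(j)
            if j not in match_right or augment(match_right[j], visited):
                match_right[j] = i
                return True
        return False

    for i in range(n_left):
        if not augment(i, set()):
            return None
    out = [-1] * n_left
    for j, i in match_right.items():
        out[i] = j
    return out


# ---------------------------------------------------------------------------
# Degree-exact occurrence via feasibility DP + bipartite matching
# ---------------------------------------------------------------------------


class _Embedder:
    def __init__(self, host: Host, tau: PatternTree, exact: bool = True):
        self.hadj = _host_adjacency(host)
        self.tau = tau
        self.padj = tau.adjacency
        self.exact = exact
        self.memo: Dict[Tuple[int, Optional[int], int], bool] = {}

    def feasible(self, p: int, p_parent: Optional[int], hu: Optional[int], hv: int) -> bool:
        """Can the pattern branch rooted at ``p`` (entered from ``p_parent``)
        embed at host vertex ``hv`` entered from ``hu``?"""
        if p in self.tau.free_leaves:
            return True
        key = (p, hu, hv)
        cached = self.memo.get(key)
        if cached is not None:
            return cached
        self.memo[key] = False  # guards against (impossible) re-entry
        res = self._feasible_internal(p, p_parent, hu, hv)
        self.memo[key] = res
        return res

    def _feasible_internal(
        self, p: int, p_parent: Optional[int], hu: Optional[int], hv: int
    ) -> bool:
        hdeg = len(self.hadj[hv])
        pdeg = len(self.padj[p])
        if self.exact:
            if hdeg != pdeg:
                return False
        elif hdeg < pdeg:
            return False
        pch = [c for c in self.padj[p] if c != p_parent]
        hch = [w for w in self.hadj[hv] if w != hu]
        if len(hch) < len(pch):
            return False
        if self.exact and len(hch) != len(pch):
            return False
        cand = [
            [j for j, w in enumerate(hch) if self.feasible(c, p, hv, w)]
            for c in pch
        ]
        return _bipartite_perfect_matching(len(pch), cand) is not None


def _trivial_cases(host: Host, tau: PatternTree) -> Optional[bool]:
    hadj = _host_adjacency(host)
    if not hadj:
        return False
    internal = tau.internal_vertices
    if not internal:
        if tau.n_vertices == 1:
            return True
        if tau.n_vertices == 2:
            return any(len(ns) > 0 for ns in hadj.values())
        raise ValidationError(
            "a pattern with more than 2 vertices must have an internal vertex"
        )
    return None


def occurs(host: Host, tau: PatternTree) -> bool:
    """Degree-exact occurrence ``T ⊃ τ`` (host viewed as an unrooted graph).

    Polynomial time: the pattern is rooted at an internal vertex and a
    feasibility table over (pattern vertex, directed host edge) is filled
    with a small bipartite matching at each internal step.
    """
    trivial = _trivial_cases(host, tau)
    if trivial is not None:
        return trivial
    emb = _Embedder(host, tau, exact=True)
    r = min(tau.internal_vertices)
    return any(emb.feasible(r, None, None, hv) for hv in emb.hadj)


def occurs_subgraph(host: Host, tau: PatternTree) -> bool:
    """Plain (non-induced) subtree containment: adjacency-preserving
    injective map, no degree constraints.  Exploratory relation only — the
    occurrence dichotomy for Galton–Watson trees is stated for the
    degree-exact relation."""
    trivial = _trivial_cases(host, tau)
    if trivial is not None:
        return trivial
    emb = _Embedder(host, tau, exact=False)
    r = min(tau.internal_vertices)
    return any(emb.feasible(r, None, None, hv) for hv in emb.hadj)


def occurs_at(host: Host, tau: PatternTree, pattern_vertex: int, host_vertex: int) -> bool:
    """Does a degree-exact embedding exist mapping ``pattern_vertex`` (which
    must be internal) to ``host_vertex``?"""
    if pattern_vertex in tau.free_leaves:
        raise ValueError("anchor pattern vertex must be internal")
    emb = _Embedder(host, tau, exact=True)
    return emb.feasible(pattern_vertex, None, None, host_vertex)


def find_embedding(host: Host, tau: PatternTree) -> Optional[Dict[int, int]]:
    """A witness embedding (pattern vertex -> host vertex), or None.

    The witness is deterministic: host root candidates are scanned in sorted
    order and children are assigned greedily preferring smaller host ids.
    """
    trivial = _trivial_cases(host, tau)
    if trivial is False:
        return None
    hadj = _host_adjacency(host)
    if trivial is True:
        verts = sorted(hadj)
        if tau.n_vertices == 1:
            return {next(iter(tau.adjacency)): verts[0]}
        for v in verts:
            if hadj[v]:
                ks = list(tau.adjacency)
                return {ks[0]: v, ks[1]: min(hadj[v])}
        return None
    emb = _Embedder(host, tau, exact=True)
    r = min(tau.internal_vertices)
    for hv in sorted(emb.hadj):
        if emb.feasible(r, None, None, hv):
            mapping: Dict[int, int] = {}
            if _assign(emb, r, None, None, hv, mapping):
                return mapping
    return None


def _assign(
    emb: _Embedder,
    p: int,
    p_parent: Optional[int],
    hu: Optional[int],
    hv: int,
    mapping: Dict[int, int],
) -> bool:
    mapping[p] = hv
    if p in emb.tau.free_leaves:
        return True
    pch = [c for c in emb.padj[p] if c != p_parent]
    hch = sorted(w for w in emb.hadj[hv] if w != hu)
    cand = [
        [j for j, w in enumerate(hch) if emb.feasible(c, p, hv, w)] for c in pch
    ]
    match = _bipartite_perfect_matching(len(pch), cand)
    if match is None:
        return False
    for c, j in zip(pch, match):
        if not _assign(emb, c, p, hv, hch[j], mapping):
            return False
    return True


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_occurs(
    host: Host, tau: PatternTree, exact: bool = True, max_host_vertices: int = 15
) -> bool:
    """Exhaustive search over injective adjacency-preserving maps.

    Same contract as :func:`occurs` (or :func:`occurs_subgraph` with
    ``exact=False``); guards against hosts larger than
    ``max_host_vertices``.  This function is the independent oracle for the
    matching-based implementation.
    """
    trivial = _trivial_cases(host, tau)
    if trivial is not None:
        return trivial
    hadj = _host_adjacency(host)
    if len(hadj) > max_host_vertices:
        raise ValueError(
            f"host has {len(hadj)} vertices; brute force is limited to "
            f"{max_host_vertices}"
        )
    padj = tau.adjacency
    free = tau.free_leaves
    # order pattern vertices so each (after the first) has an earlier neighbour
    order: List[int] = [next(iter(padj))]
    seen = {order[0]}
    frontier = list(padj[order[0]])
    while frontier:
        v = frontier.pop()
        if v in seen:
            continue
        seen.add(v)
        order.append(v)
        frontier.extend(padj[v])
    anchor: List[Optional[int]] = [None]
    for v in order[1:]:
        anchor.append(next(u for u in padj[v] if u in seen and order.index(u) < order.index(v)))

    host_vertices = sorted(hadj)

    def ok_final(mapping: Dict[int, int]) -> bool:
        for p, hv in mapping.items():
            if p in free:
                continue
            if exact:
                if len(hadj[hv]) != len(padj[p]):
                    return False
                if {mapping[q] for q in padj[p]} != set(hadj[hv]):
                    return False
            else:
                if len(hadj[hv]) < len(padj[p]):
                    return False
        return True

    def backtrack(i: int, mapping: Dict[int, int], used: Set[int]) -> bool:
        if i == len(order):
            return ok_final(mapping)
        p = order[i]
        if anchor[i] is None:
            candidates = host_vertices
        else:
            candidates = hadj[mapping[anchor[i]]]
        for hv in candidates:
            if hv in used:
                continue
            if p not in free and exact and len(hadj[hv]) != len(padj[p]):
                continue
            mapping[p] = hv
            used.add(hv)
            if backtrack(i + 1, mapping, used):
                return True
            del mapping[p]
            used.remove(hv)
        return False

    return backtrack(0, {}, set())


# ---------------------------------------------------------------------------
# Snowflake detection
# ---------------------------------------------------------------------------


def snowflake_central_vertices(T: LeafLabelledTree) -> Set[int]:
    """All snowflake centres of a binary tree: the interior vertices whose
    edge-distance to every leaf is at least 3 (multi-source BFS from the
    leaves; linear time)."""
    if T.d != 2:
        raise ValueError("snowflake centres are defined for binary trees (d=2)")
    dist = T.nearest_leaf_distances()
    return {v for v, dv in dist.items() if dv >= 3}


def count_snowflake_centers(T: LeafLabelledTree) -> int:
    """``X_T``, the number of snowflake centres of ``T``."""
    return len(snowflake_central_vertices(T))


def snowflake_centers_by_embedding(T: LeafLabelledTree) -> Set[int]:
    """Snowflake centres found by the generic degree-exact embedding engine
    (anchor = the pattern's central vertex).  Cross-check for
    :func:`snowflake_central_vertices`."""
    tau = snowflake_pattern()
    emb = _Embedder(T, tau, exact=True)
    return {hv for hv in emb.hadj if emb.feasible(0, None, None, hv)}


# ---------------------------------------------------------------------------
# Realizability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Realizability:
    """Whether a tree can be rooted with all out-degrees in a given support.

    Both rooting conventions are reported: at a vertex, and at the midpoint
    of an edge (the phylogenetic convention, which inserts a degree-2 root).
    The truthiness is their disjunction.
    """

    vertex_rooted: bool
    edge_rooted: bool

    def __bool__(self) -> bool:
        return self.vertex_rooted or self.edge_rooted


def is_realizable(
    tau: Union[PatternTree, Adjacency], X: OffspringDistribution
) -> Realizability:
    """Can ``tau`` be rooted so that every out-degree lies in ``support(X)``?

    Rooting at vertex ``v`` gives ``v`` out-degree ``deg(v)`` and every other
    vertex ``deg - 1``.  Rooting on an edge subdivides it with a new root of
    out-degree 2 and gives every original vertex ``deg - 1``.  A pattern is
    realizable iff it can be the realisation of a GW(X) tree, which is what
    separates asymptotically-certain patterns from impossible ones.
    """
    adj = tau.adjacency if isinstance(tau, PatternTree) else tau
    support = set(X.support)
    degrees = {v: len(ns) for v, ns in adj.items()}
    all_minus_one = all(dv - 1 in support for dv in degrees.values())
    vertex_rooted = any(
        degrees[v] in support
        and all(degrees[u] - 1 in support for u in degrees if u != v)
        for v in degrees
    )
    has_edge = any(degrees.values())
    edge_rooted = bool(has_edge and 2 in support and all_minus_one)
    return Realizability(vertex_rooted=vertex_rooted, edge_rooted=edge_rooted)
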