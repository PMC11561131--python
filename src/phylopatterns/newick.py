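"""Newick reading and writing.

The dialect is purely topological: internal vertices are unlabelled and no
branch lengths are emitted; branch lengths present on input are parsed (via
dendropy) and discarded with a warning.  Leaf names must be the integers
``1..n`` for unrooted leaf-labelled trees; for rooted ordered trees the leaf
names are ignored and child order is preserved.
"""

from __future__ import annotations

import io
import warnings
from typing import Dict, List, Optional, Union

import dendropy

from .trees import Adjacency, LeafLabelledTree, RootedOrderedTree, ValidationError

__all__ = [
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
]


class NewickParseError(ValueError):
    """The input is not a syntactically valid Newick string."""


def _dendropy_parse(text: str, suppress_leaf_taxa: bool = False) -> dendropy.Tree:
    if not text.strip().endswith(";"):
        raise NewickParseError("Newick string must be terminated by ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            # patterns repeat the free-leaf marker "_", which must not be
            # treated as a taxon
            suppress_leaf_node_taxa=suppress_leaf_taxa,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises various error classes
        raise NewickParseError(f"malformed Newick string: {exc}") from exc
    if any(e.length is not None for e in tree.edges()):
        warnings.warn(
            "branch lengths in Newick input are ignored (topology only)",
            UserWarning,
            stacklevel=3,
        )
    return tree


def _leaf_name(node: dendropy.Node) -> Optional[str]:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def parse_newick(
    text: str, rooted: bool = False, d: Optional[int] = None
) -> Union[LeafLabelledTree, RootedOrderedTree]:
    """Parse a Newick string.

    With ``rooted=True``, returns a :class:`RootedOrderedTree` preserving child
    order (leaf names are ignored).  Otherwise returns a
    :class:`LeafLabelledTree`; leaf names must be integers, and the vertex
    degrees must all be 1 or ``d + 1`` (``d`` inferred from the maximum degree
    when not given).  A two-leaf string ``"(1,2);"`` denotes the single-edge
    tree.
    """
    tree = _dendropy_parse(text)
    if rooted:
        seq: List[int] = []
        for node in tree.preorder_node_iter():
            seq.append(len(node.child_nodes()))
        return RootedOrderedTree(seq)

    ids: Dict[dendropy.Node, int] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        ids[node] = i
    adj: Adjacency = {i: [] for i in ids.values()}
    leaf_labels: Dict[int, int] = {}
    for node, i in ids.items():
        for child in node.child_nodes():
            j = ids[child]
            adj[i].append(j)
            adj[j].append(i)
    for node, i in ids.items():
        if not node.child_nodes():
            name = _leaf_name(node)
            if name is None:
                raise NewickParseError("unnamed leaf in Newick string")
            try:
                leaf_labels[i] = int(name)
            except ValueError as exc:
                raise ValidationError(
                    f"leaf name {name!r} is not an integer label"
                ) from exc
    # A top-level bifurcation with exactly two leaves is the single-edge tree:
    # suppress the synthetic root vertex.
    root = ids[tree.seed_node]
    if len(adj) == 3 and len(adj[root]) == 2 and len(leaf_labels) == 2:
        a, b = adj[root]
        adj = {a: [b], b: [a]}
    if d is None:
        degs = {len(ns) for v, ns in adj.items() if v not in leaf_labels}
        d = max(degs) - 1 if degs else 2
    return LeafLabelledTree(adj, leaf_labels, d=d)


def write_newick(tree: Union[LeafLabelledTree, RootedOrderedTree]) -> str:
    """Serialise a tree to Newick.

    Unrooted leaf-labelled trees are written rooted at the internal vertex
    adjacent to leaf 1, with child subtrees in sorted (canonical) order, so
    the output is deterministic.  Rooted ordered trees keep their child order;
    their leaves are written as ``L1, L2, ...`` in preorder.
    """
    if isinstance(tree, LeafLabelledTree):
        return _write_unrooted(tree)
    if isinstance(tree, RootedOrderedTree):
        return _write_rooted(tree)
    raise TypeError(f"unsupported tree type: {type(tree)!r}")


def _write_unrooted(tree: LeafLabelledTree) -> str:
    adj = tree.adjacency
    labels = tree.leaf_labels
    if tree.n_leaves == 2:
        a, b = sorted(labels.values())
        return f"({a},{b});"
    leaf1 = tree.label_to_vertex()[1]
    root = adj[leaf1][0]

    def sub(v: int, parent: int) -> str:
        if v in labels:
            return str(labels[v])
        parts = sorted(sub(w, v) for w in adj[v] if w != parent)
        return "(" + ",".join(parts) + ")"

    parts = sorted(sub(w, root) for w in adj[root])
    return "(" + ",".join(parts) + ");"


def _write_rooted(tree: RootedOrderedTree) -> str:
    ch = tree.children_lists()
    counter = iter(range(1, tree.n_leaves + 1))

    def sub(v: int) -> str:
        if not ch[v]:
            return f"L{next(counter)}"
        return "(" + ",".join(sub(c) for c in ch[v]) + ")"

    return sub(0) + ";"


def read_newick_file(path, rooted: bool = False, d: Optional[int] = None) -> List:
    """Read one tree per non-empty line."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(parse_newick(line, rooted=rooted, d=d))
    return out


def write_newick_file(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")
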