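"""Shared fixtures and reference tree builders."""

import numpy as np
import pytest

from phylopatterns import LeafLabelledTree

# a seed fixed once for the whole suite; every stochastic test derives its
# stream from it so reruns are bit-for-bit identical
SUITE_SEED = 20240619


@pytest.fixture
def rng():
    return np.random.default_rng(SUITE_SEED)


def make_rng(salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((SUITE_SEED, salt)))


def perfect_snowflake_tree() -> LeafLabelledTree:
    """The 12-leaf binary tree that is exactly one snowflake: a centre,
    3 neighbours, 6 grand-neighbours, 12 leaves."""
    adj = {0: []}
    labels = {}
    nxt, lbl = 1, 1
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
                labels[c] = lbl
                lbl += 1
    return LeafLabelledTree(adj, labels, d=2)


def caterpillar_tree(n: int) -> LeafLabelledTree:
    """The caterpillar on n leaves: internal vertices form a path; every
    internal vertex is adjacent to a leaf, so it has no snowflake."""
    assert n >= 4
    adj = {}
    labels = {}
    for i in range(n - 3):
        adj.setdefault(i, []).append(i + 1)
        adj.setdefault(i + 1, []).append(i)
    nxt, lbl = n - 2, 1
    for i in range(n - 2):
        extra = 2 if i in (0, n - 3) else 1
        for _ in range(extra):
            adj.setdefault(i, []).append(nxt)
            adj[nxt] = [i]
            labels[nxt] = lbl
            lbl += 1
            nxt += 1
    return LeafLabelledTree(adj, labels, d=2)


def balanced_tree(half_depth: int) -> LeafLabelledTree:
    """Two complete rooted binary trees of the given depth joined by a
    central edge; all leaves at distance half_depth + 1 from the centre."""
    adj = {}
    labels = {}
    counter = [0]

    def build(depth: int) -> int:
        v = counter[0]
        counter[0] += 1
        adj[v] = []
        if depth == 0:
            labels[v] = len(labels) + 1
            return v
        for _ in range(2):
            c = build(depth - 1)
            adj[v].append(c)
            adj[c].append(v)
        return v

    r1 = build(half_depth)
    r2 = build(half_depth)
    adj[r1].append(r2)
    adj[r2].append(r1)
    return LeafLabelledTree(adj, labels, d=2)
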