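# Methods

This note records the models, algorithms, and numerical conventions behind
`phylopatterns`, and the design choices made where several reasonable
options existed.

## Trees and their representations

Three tree types are used.

**Unrooted leaf-labelled d-ary trees** (`LeafLabelledTree`): every vertex has
degree 1 (leaf) or `d+1` (internal); leaves carry the labels `1..n`.  For
`d=2` (binary phylogenetic trees) with `n ≥ 3` there are `2n-2` vertices and
`2n-3` edges.  Stored as an adjacency dict plus a leaf-label map; all
invariants (degrees, label set, connectivity, acyclicity) are checked at
construction, and validation errors name the offending vertex.  Distances
are always counted in edges.

**Rooted ordered (plane) trees** (`RootedOrderedTree`): stored as the
preorder out-degree sequence (the Łukasiewicz word), which is the canonical
compact encoding — a sequence is a tree iff the walk with steps
`out_degree - 1` stays non-negative until it ends at `-1`.  Ulam–Harris
addresses, depths, children lists, subtree sizes and balls are derived from
the sequence in linear time.  The ball `[T]_k` keeps all vertices at depth
`≤ k` and zeroes the out-degrees at depth exactly `k`, so it is again a
plane tree and exact equality of balls is tuple equality of their codes.

**Pattern trees** (`PatternTree`): finite unlabelled trees with vertices
partitioned into *internal* (degree ≥ 2) and *free leaves* (degree ≤ 1).
The roles are forced by the degrees; the partition is kept explicit because
the two classes carry different embedding semantics.

**Canonical codes.**  Leaf-labelled trees are coded by rooting at the leaf
labelled 1 (a canonical choice) and recursively sorting child codes; two
trees get equal codes iff they are isomorphic respecting labels.  Plane
trees have an ordered code (the preorder sequence itself) and an unordered
code (recursive sorted child codes).  Unlabelled free trees are coded by
rooting at the centroid (minimum over the ≤ 2 centroids).

**Newick dialect.**  Purely topological: internal vertices unlabelled, no
branch lengths written; branch lengths on input are parsed (via dendropy)
and discarded with a warning.  Unrooted trees are written rooted at the
internal vertex adjacent to leaf 1, children in sorted order, so output is
deterministic.  A two-leaf tree is `"(1,2);"`.  In pattern Newick, leaves
named `_` are free leaves.

## Exact enumeration

All identities are evaluated with Python big integers and
`fractions.Fraction`; no float enters any identity check.  The symmetry
constants `12!/(2^9·3!) = 155925` (snowflake arrangements) and `22!/2^16`
(two-snowflake arrangements) are computed from their orbit–stabilizer
definitions, never hard-coded.  The convention `B(2) = 1` makes the
forest-decomposition bijection total and supplies the `i = 0` term of the
`W(n)` summation.

Floats appear only in the `*_float` evaluators used for asymptotics at
`n > 10^4`, where factorials are impractical: ratios of factorials become
differences of `scipy.special.gammaln`, which is stable at `n = 10^6`.
The exact leading corrections of the scaled densities are
`|S(n)|/B(n) · 2^7/n = 1 - 29/n + O(1/n²)` and
`W(n)/B(n) · 2^14/n² = 1 - 117.5/n + O(1/n²)`; tests assert agreement with
the limit constants to one unit in the fourth significant figure at
`n = 10^6`, which is what these corrections permit.

Cross-check oracles: the exhaustive leaf-insertion generator (each tree on
`n` leaves arises exactly once from a tree on `n-1` by inserting leaf `n`
into an edge) validates `B(n)` for small `n`; a brute-force sum over set
partitions validates `N(n,k)`; the generalized-binomial series of
`1 - √(1-2x)` validates `R(n)/n!`.

The ordered/unrooted double-counting identity
`|T_{n-1}| · n! = |T~_n| · n · (d!)^{(n-2)/(d-1)}` is checked for all `n`
with `(n-2) % (d-1) == 0` — the condition for d-ary trees with `n` leaves
to exist (for `d = 2` that is every `n`; for `d = 3`, even `n`).

## Samplers

All samplers take an explicit `numpy.random.Generator`; there is no global
state.  Experiments spawn one child generator per replicate from
`SeedSequence(seed)`, so runs are reproducible bit-for-bit and replicate
streams are independent.

**Size-conditioned Galton–Watson trees.**  For the critical offspring law
`X = d·Bernoulli(1/d)` the conditioned tree is uniform over ordered d-ary
trees with `n` vertices.  Sampling is by the cycle lemma: the out-degree
multiset is deterministic (`(n-1)/d` internal vertices), a uniform shuffle
gives an exchangeable sequence with step sum `-1`, and exactly one cyclic
rotation (starting after the first minimum of the partial-sum walk) is a
valid preorder word.  This is exact uniformity in `O(n)`, not an asymptotic
approximation.  For general finite-support laws the i.i.d. sequence is
drawn conditioned on its sum by rejection before rotating; plain rejection
sampling of whole GW realisations is kept as an independent test oracle.
Impossible sizes raise errors naming the congruence condition.

**Uniform leaf-labelled trees.**  A uniform ordered d-ary tree with `n-1`
leaves, one leaf grafted to the root, a uniform random labelling of the `n`
leaves, then ordering and rooting discarded.  The double-counting identity
above makes the output exactly uniform over leaf-labelled d-ary trees; the
test suite verifies this exhaustively (all ordered trees × all labellings
cover every tree equally often at `n = 4, 5`) and statistically
(chi-square at `n = 5`).

**Yule–Harding.**  Iterative: start from the two-leaf tree, attach each new
leaf at the subdivided midpoint of a uniformly chosen pendant edge
(topological, no branch lengths).  The rooted variant returns the plane
tree with sibling order randomised, so the leaf count of the first root
subtree is uniform on `{1, .., n-1}` — the classical root-split law, tested
by chi-square.  The unrooted variant suppresses the degree-2 root and
applies a uniform final leaf relabelling, making the labelled law
exchangeable (the shape distribution is what matters; arrival-order labels
would make label-dependent events degenerate).

**Kesten balls.**  The local limit of the size-conditioned trees is the
infinite spine tree: spine vertices receive `X* - 1` grafted independent
GW(X) subtrees, `X*` size-biased (`P(X*=k) = k P(X=k)/E(X)`, exact
rationals).  `sample_kesten_ball` returns the radius-`k` ball exactly in
distribution: grafted subtrees are *depth*-truncated at their remaining
budget (the ball never looks deeper), and the spine child's position among
the `X*` slots is uniform — the limit theorem does not fix an interleaving,
and the choice is distributionally irrelevant for unordered functionals.
Non-critical laws are rejected (tilting to criticality is out of scope).
`sample_spine_walk` samples the off-spine edge counts `S_k` alone, for
walk-level diagnostics at large `k` without building balls.

## Pattern occurrence

**Semantics.**  `T ⊃ τ` means a *degree-exact* embedding: an injective,
adjacency-preserving map under which every internal pattern vertex lands on
a host vertex of equal degree with all host neighbours covered by pattern
neighbours; free leaves are unconstrained (they stand for hanging
subtrees).  This is the only reading under which (i) the snowflake
convention (each free leaf is a rooted subtree on ≥ 1 leaves), (ii) the
realizability dichotomy (a non-realizable pattern such as the 4-vertex path
never occurs in a binary host), and (iii) the d-ary generalisation are
simultaneously consistent.  Plain subtree containment is exposed separately
as `occurs_subgraph` for exploration, with no dichotomy claims; note that
deleting a free leaf is monotone for the plain relation but *not* for the
degree-exact one (it changes the required degree of the neighbour).

**Algorithm.**  The pattern is rooted at an internal vertex; a feasibility
table over (pattern vertex, directed host edge) is filled lazily, where an
internal step requires equal degrees and a perfect bipartite matching of
pattern children against host neighbours (a small augmenting-path matcher;
both sides have ≤ d+1 vertices).  Overall polynomial in host × pattern
size.  Witness embeddings are reconstructed deterministically (host
candidates scanned in sorted order).  The exhaustive backtracking oracle
`brute_force_occurs` implements the same contract independently and the two
are compared over every host with ≤ 11 vertices (all leaf-labelled trees up
to 6 leaves, all plane binary trees up to 11 vertices) × every pattern with
≤ 7 vertices.

**Snowflakes.**  A vertex of a binary tree is a snowflake centre iff its
edge-distance to every leaf is ≥ 3; `snowflake_central_vertices` is a
multi-source BFS from the leaves (linear time) and is cross-checked against
the embedding engine anchored at the pattern centre on random 30-leaf
trees.

**Realizability.**  Both rooting conventions are evaluated and reported
separately: rooting at a vertex (root keeps its full degree) and rooting on
a subdivided edge (new degree-2 root; the phylogenetic convention).  The
snowflake is edge-rootable but not vertex-rootable for the binary offspring
law, so both flags are kept visible rather than silently preferring one.

## Monte-Carlo experiments and problem sizes

Each experiment returns point estimates with their standard error
(sample SD / √reps).  Where an exact value exists (`E(X_n) = |S(n)|/B(n)`),
agreement is asserted within 3 SE, with a Bernoulli-scale SE floor
(√(p/reps)) so the band is well defined when only a handful of centres is
observed (at `n = 12` the exact mean is ≈ 2.4·10⁻⁴).  Where the theory
provides only a limit (occurrence probabilities, `P(X_n = 0)`), the checks
are property-based: monotonicity along the grid within 3 pooled SE, the
bound `P(X_n=0) ≤ 1 - 2^-7`, and near-certainty (> 0.95) of snowflake
occurrence at `n = 1000`.

Default study sizes: occurrence curves on `n ∈ {50, 200, 1000}` with 500
replicates per point; moment agreement at `n ∈ {12, 50, 100}` with 10⁴
replicates; ball total-variation at radius 2 between 2001-vertex
conditioned trees and Kesten balls with 10⁴ draws of each.  These sizes put
the 3-SE bands at or below ~10% of the target quantities while keeping the
whole suite runnable on a laptop in a few minutes.  The TV distance is
computed on the union of observed ball supports, which biases it slightly
downward; the radius cap (≤ 3) keeps support coverage high.  For the
snowflake on binary trees the curves use the linear-time centre criterion
rather than the generic embedding engine; the equivalence of the two is
itself a tested claim.

## Known limitations

* Exact identity evaluation is practical up to `n` in the low thousands
  (big-integer factorials); beyond that only the log-Gamma float path is
  provided.
* The generic conditioned-GW sampler falls back to rejection on the
  out-degree sum for non-d-ary laws, which degrades for large `n`; all
  d-ary laws (the cases with a uniformity theorem) use the O(n) exact path.
* Exhaustive d-ary enumeration for `d > 2` de-duplicates grafted labelled
  trees and is limited to small `n`; it exists as an oracle, not a tool.
* Level-k networks, branch lengths, multifurcations beyond `d+1`, and
  exponential tilting of non-critical offspring laws are out of scope.
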