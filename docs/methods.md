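# Methods

## The model

A scaffold graph is an undirected graph `G = (V, E, w)` with an even number
of vertices, integer edge weights `w : E → ℕ`, and a perfect matching
`M ⊆ E` of *contig edges*; the remaining edges are *links*. A
*σ_p-σ_c-cover* is a matching `S` among the links such that `G[S ∪ M]`
decomposes into exactly `σ_p` paths and `σ_c` cycles. Because `M` is
perfect and kept in full, every component automatically contains each of
its vertices' matching partners, i.e. is alternating; `classify_selection`
asserts this rather than re-checking it. Two useful identities follow
directly and are used throughout: every σ_p-σ_c-cover selects exactly
`|M| − σ_p` links, and a cycle consumes at least two contig edges, so
`σ_c ≤ ⌊|M|/2⌋`.

`σ_p`/`σ_c` are treated as **exact** component counts (this is what both
dynamic-programming tables index); `solve_at_most` maximises over all
`(p ≤ σ_p, c ≤ σ_c)` by reading the full root table of a single run.
Link weights enter the objective; contig-edge weights never do (they are
forced into every solution). Weights are integers, which keeps DP maxima
tie-free up to the documented deterministic tie-breaks.

## Tree solver

With the input a tree, solutions contain no cycles. The table entry
`[c, i, j]_v` is the best weight of an `i`-path cover of the subtree made
of `v` plus its first `j` children's subtrees, with exactly
`c ∈ {0, 1}` selected links at `v`. The inner index `j` is what makes the
child-count splitting polynomial. A subtle convention makes the counting
exact: a vertex whose contig partner lies outside the processed subtree
and which touches no selected link belongs to *no* component yet — its
path materialises only when its contig edge is processed. The four
recurrences distinguish contig vs link child edge and `c`; for the
selected-link case the path through `uv` either *merges* with the
component already containing `v` (its partner is among the first `j`
children) or merely *extends* to `v`. `−∞` is an explicit sentinel
(weight-0 covers are feasible). The root is the lexicographically
smallest vertex, children are ordered lexicographically, and maxima keep
the first-listed option, so reconstruction is deterministic. Forests are
solved per component and recombined by an exact knapsack over the split
of `σ_p`.

Correctness is enforced empirically in two layers: every final table
entry is compared against an exhaustive enumeration of subtree covers on
small instances, and the returned optimum is compared against the
brute-force oracle on hundreds of random trees.

## Treewidth solver

The solver runs over a *nice* tree decomposition. A bag state is
`(d, P, p, c)`: the degree (0/1/2) of each bag vertex in the partial
solution (selected links plus contig edges introduced so far), an
involution `P` on the degree-1 vertices — pair `(u,v)` for a partial
`u–v` path, fixed point `(u,u)` for a path dangling from `u` into the
forgotten region — and counters `p`, `c` of completed paths/cycles
avoiding all degree-1 bag vertices. Transitions:

* *introduce vertex*: degree pinned to 0;
* *introduce edge*: contig edges are **forced** in (covers contain all of
  `M`; no weight added), links take the better of inclusion (+`w`) and
  exclusion; inclusion updates `P` by the five possible couplings of the
  endpoints' partial paths (cycle closure increments `c`, merging two
  dangling paths increments `p`);
* *forget `v`*: degree 1 splits three ways — the dangling path ends at
  another bag vertex `u` (`uv → uu`), or closes into a counted path
  (`p+1`);
* *join*: the two children's involutions are composed by tracing the
  maximal alternating chains of their union; open/open chains become
  pairs, open/free chains fixed points, free/free chains completed paths,
  closed chains completed cycles. This chain-tracing generalises counting
  only the directly shared pairs/fixed points, which would miss longer
  alternating cycles and paths; the generalisation is validated against
  the brute-force oracle.

One run tabulates all `(p ≤ σ_p, c ≤ σ_c)` simultaneously; the optimum per
count pair is read off the empty root bag, and backpointers reconstruct a
witness cover. The number of involutions per bag is of order
`(tw+2)^(tw+1)` (asserted as a resource guard), so a width cap (default
12) refuses unreasonable decompositions with a clear error.

## Tree decompositions

`greedy_fillin` eliminates, at each step, the vertex whose neighbourhood
needs the fewest fill edges (lexicographic tie-break), and builds bags
from elimination neighbourhoods; components yield a bag forest whose
roots are chained (joining bags without shared vertices preserves
validity). `make_nice` inserts forget/introduce chains between original
bags, binarises joins, and attaches each graph edge to exactly one
introduce-edge bag — directly above the first introduce-vertex bag (in
construction order) containing both endpoints, which always exists; an
assertion checks the edge-introduction multiset equals `E`. Width never
increases. Only greedy fill-in is provided; computing optimal treewidth
is out of scope.

## Kernelization of restricted scaffolding

Restricted scaffolding fixes all path lengths to `ℓ_p` (odd, in edges)
and all cycle lengths to `ℓ_c`, with `w(M) = 0`. Necessary condition
`σ_p(ℓ_p+1) + σ_c·ℓ_c = |V|` is checked up front (failure ⇒ NO). The
structural frame is the *cycle core*: `V°` (vertices on cycles, i.e.
endpoints of non-bridge edges), its convex hull `V*` (computed by pruning
non-`V°` leaves, equivalent to the shortest-path definition on the bridge
forest), pendant trees hanging off `V*`, and the contracted core `G†`
obtained by contracting degree-2 chains of `G[V*]` (bare-cycle components
collapse to a self-loop vertex by convention).

Rules, applied tree rules first and restarting after every change:

1. **Isolated paths** are split into length-`ℓ_p` pieces from the
   lexicographically smallest endpoint (`σ_p−1`, `k −= w(q)`); a piece
   that cannot be completed proves NO. Parity guarantees the removed
   connector is a link.
2. **Pendant trees** that branch or reach height ≥ `ℓ_p` are pruned at
   the meeting point (LCA) of the deepest leaf `u` and the deepest
   feasible far end `w` of a length-`ℓ_p` alternating path from `u`;
   if no such path exists inside the tree, the leaf is uncoverable: NO.
   Short bare-path pendants are final kernel shape and are *not* touched —
   their covering path legitimately continues into the core.
3. A pendant attached by a link `e` forces `e` into every solution, so
   all other non-contig edges at its root are deleted.
4. **Long degree-2 chains** (longer than `max(ℓ_p,ℓ_c) + ℓ_p + 1`) carry
   no solution cycle, so the cover pattern repeats with period `ℓ_p+1`:
   the first period's weights are folded one period down and the period
   is contracted (`σ_p−1`).
5. Two period-length chains meeting at a pendant root `w` (with `γ > 0`
   pendant edges) are forced up to a cyclic shift by `γ`; one chain is
   contracted onto the other with indices realigned by
   `i ↦ (i−γ) mod (ℓ_p+1)`. The two chains must be vertex-disjoint except
   at `w` — without this requirement the rule misfires when the chain
   wraps a short cycle, which an oracle counterexample exposed during
   development.
6. A chain between two pendant roots dispatches on the congruences of
   `γ = |p| mod (ℓ_p+1)` and the pendant sizes: an end link is deleted,
   the chain is re-attached to the deep end of one pendant (canonicalising
   an ambiguous choice), the root is stripped to its forced edges, or the
   instance is NO. A dispatch that would delete or re-route a contig edge
   is answered by NO or by skipping the site, respectively.

Contractions merge vertices through a helper that refuses (and rolls
back) when a parallel edge or self-loop would arise — skipping a site is
always decision-safe. Every application strictly decreases the measure
`(|V| + |E|, total pendant edges)` (asserted), so reduction terminates;
the perfect-matching invariant is re-validated after each step. The trace
records every rule application with its `σ_p`/`k` deltas; replaying the
deltas maps the original parameters to the reduced ones. Solution
*lifting* (mapping a kernel witness back) is out of scope; decision and
optimal weight are preserved, which the tests verify by brute force on
both sides, NO outcomes included.

For fully reduced yes-instances the kernel bound
`|V| ≤ 11ℓ·FES`, `|E| ≤ (11ℓ+1)·FES` is asserted, along with the
intermediate chain-counting bound `|V| ≤ ℓ(|V†| + 3|E†|)` whenever the
contracted core is non-degenerate (a hull that is a single bare cycle
collapses to one self-loop vertex, where chain counting does not apply;
the 11ℓ·FES bound itself still holds and is always checked).

## Synthetic generators

All generators are pure functions of their arguments with one private
PRNG per call; identical seeds give byte-identical SGF output.

* `gen_tree_instance` attaches contigs one at a time to a random existing
  vertex: a tree whose matching edges are tree edges, link weights
  uniform on [1, 20] (a plausible paired-end support range; matching
  edges weigh 0).
* `gen_bounded_tw_instance` adds up to `max_extra_edges` random links to
  such a tree, so FES is bounded by construction; 17 contigs with 10
  extras reproduces the 34-vertex / 43-edge shape of a small viral
  scaffold graph.
* `gen_planted_instance` builds `σ_p` paths and `σ_c` cycles of known
  weight and adds decoy links each strictly lighter than every planted
  link. Since any cover with the same counts selects exactly `|M| − σ_p`
  links, swapping any planted link for a decoy strictly loses weight:
  the plant is the *provably unique* optimum, not just a likely one.
  An `acyclic` mode restricts decoys to forest-preserving positions so
  the tree solver applies.
* `gen_rsca_instance` plants `σ_p` length-`ℓ_p` blocks and `σ_c`
  length-`ℓ_c` cycles, then obfuscates while keeping the plant feasible:
  blocks chained into isolated long paths (rule 1 fodder), blocks closed
  into long cycles (rule 4), full-block pendant chains on cycle vertices
  (rules 2–3), and *bent* blocks whose prefix dangles as a short pendant
  off the chain (rules 3, 5, 6). `k` is the weight the planted solution
  keeps, so every instance is yes by construction.

What the generators do **not** emulate: read-mapping noise models,
insert-size distributions, weight correlations along the genome, and the
heavy-tailed degree spikes of repeat-induced hubs. Passing tests
therefore demonstrate algorithmic correctness on the targeted structural
classes (trees, bounded-FES graphs, reducible instances), not end-to-end
assembly quality on real libraries.

## Test strategy and sizes

Brute force (`oracle`) enumerates link matchings with branch pruning
(guard: ≤ 25 links) and is the ground truth everywhere: both DPs are
checked against it on 100 random trees (≤ 7 contigs, `σ_p ≤ 4`) and 100
random sparse graphs (≤ 6 contigs, ≤ 4 extra links, all `σ_p ≤ 3`,
`σ_c ≤ 2`); reduction is checked for decision preservation on 200 mixed
random restricted instances (≤ 24 vertices) and for the kernel bound on
100 seeded reducible instances. These sizes keep the whole suite around
a few seconds while covering every rule and transition; the acceptance
script reports the worst kernel ratio `|V|/(ℓ·FES)` over its suite
(about 4.4, comfortably under the guaranteed 11).
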