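# scaffex

Exact combinatorial solvers and preprocessing for **genome scaffolding** on
scaffold graphs.

After assembly, a genome is a pile of contigs; scaffolding orders and
orients them. The *scaffold graph* `(G, M)` models this: every contig is a
pair of vertices (its two extremities) joined by a *contig edge*, and the
contig edges form a perfect matching `M`. Every other edge (a *link*)
`uv` with contig edges `uu'`, `vv'` carries a non-negative integer weight
`w(uv)` — the confidence (e.g. from paired-end read mappings) that contig
`uu'` is succeeded by contig `vv'` oriented `u'–u–v–v'`.

The scaffolding problem asks, given `σ_p, σ_c, k ∈ ℕ`: is there a matching
`S` among the links such that `G[S ∪ M]` consists of exactly `σ_p`
alternating paths and `σ_c` alternating cycles (the linear and circular
chromosomes) with `w(S) ≥ k`? All solvers return the maximum-weight such
cover together with a witness. The problem is NP-hard in general, but real
scaffold graphs are very sparse — their feedback edge set number
`FES = |E| − |V| + #components` is far below the input size — and this
package implements the exact approaches that exploit that structure:

* **`tree_dp`** — an `O(n·σ_p²)` dynamic program when the graph is a tree
  (forests are combined by a knapsack over components).
* **`treewidth_dp`** — a dynamic program over a nice tree decomposition,
  running in `O(tw^tw · σ_p · σ_c · n)`; state = per-bag degrees in the
  partial solution, an involution pairing the degree-1 bag vertices by
  partial paths, and counters of completed paths/cycles.
* **`decomposition`** — greedy fill-in tree decompositions and their
  conversion to nice (leaf / introduce-vertex / introduce-edge / forget /
  join) form.
* **`kernel`** — for *restricted* scaffolding (all paths of length exactly
  `ℓ_p`, all cycles exactly `ℓ_c`, `w(M) = 0`), six reduction rules that
  shrink any instance to an equivalent kernel with at most `11·ℓ·FES`
  vertices and `(11ℓ+1)·FES` edges, `ℓ = max(ℓ_p, ℓ_c)`.
* **`stats`** — the structural parameters used to profile real scaffold
  graphs: FES, a greedy FVS upper bound, h-index, degeneracy, and the
  cycle-core / pendant-tree / contracted-core decomposition.
* **`generate`** — seeded synthetic instances: random trees, bounded-FES
  sparse graphs, planted-unique-optimum instances, and reducible
  restricted instances.
* **`oracle`** — brute-force exact solvers (the ground truth for every
  other module's tests).

## Worked example

Generate a sparse instance with 5 contigs and 2 extra links, profile it,
and solve it:

```text
$ scaffex generate --kind sparse --seed 7 --n-contigs 5 --max-extra-edges 2 --out demo.sgf
$ scaffex stats demo.sgf
|V|   |E|   min/max/avg degree   FES   FVS(ub)   h   dcy
10    11    1 / 4 / 2.20       2     1         2   2

$ scaffex solve demo.sgf --sigma-p 2 --sigma-c 1
optimum weight: 33
paths: 2  cycles: 1
S v0000 v0005
S v0002 v0006
S v0003 v0007
```

The three `S` lines are the selected links: together with the five contig
edges they form two linear scaffolds (`v0001–v0000–v0005–v0004` and the
lone contig `v0008–v0009`) and one circular scaffold through contigs
`v0002–v0003` and `v0006–v0007`, of total link weight 33 — the maximum over
all covers with exactly those component counts. Asking instead for a
single linear chromosome (`--sigma-p 1 --sigma-c 0`) yields weight 47.

Kernelization of a restricted instance (4 paths of length 3, one
4-cycle, 20 vertices) shrinks it to its 4-vertex cycle core in 6 rule
applications, rewriting `σ_p` and `k` on the way:

```text
$ scaffex generate --kind rsca --seed 5 --sigma-p 4 --sigma-c 1 --ell-p 3 --ell-c 4 --out r.sgf
$ scaffex kernelize r.sgf
reduced: |V|=4 |E|=4 FES=1 sigma_p=0 k=29 rules=6
```

The same functionality is available as a library
(`scaffex.solve_tw`, `scaffex.solve_on_tree`, `scaffex.reduce_instance`,
...); SGF is the native plain-text format (see `scaffex/graph_io.py`),
with DOT export and GraphML round-tripping.

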