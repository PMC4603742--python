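"""Structural parameters of scaffold graphs.

Real scaffold graphs are sparse and tree-like: the number of independent
cycles (the feedback edge set size, FES = |E| - |V| + #components) is far
below the vertex count.  This module computes the parameters used to
characterise that sparsity -- FES, a greedy feedback-vertex-set upper bound,
the h-index and the degeneracy -- together with the cycle-core decomposition
(the convex hull of all cycles, its pendant trees, and the multigraph
obtained by contracting its degree-2 chains) that drives the kernelization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx


@dataclass(frozen=True)
class GraphProfile:
    n_vertices: int
    n_edges: int
    min_degree: int
    max_degree: int
    avg_degree: float
    fes: int
    fvs_ub: int
    h_index: int
    degeneracy: int


@dataclass
class CycleCore:
    """Cycle vertices, their convex hull and the pendant trees hanging off it.

    ``v_circle`` are vertices lying on some cycle; ``v_star`` adds all
    vertices on paths between them (the convex hull); ``pendant_trees`` maps
    each hull vertex to the vertex set of the tree hanging from it (root
    included), and ``stray_trees`` collects acyclic components that touch no
    hull vertex at all.
    """

    v_circle: set[str]
    v_star: set[str]
    pendant_trees: dict[str, set[str]] = field(default_factory=dict)
    stray_trees: list[set[str]] = field(default_factory=list)


@dataclass
class ContractedCore:
    """Multigraph from contracting degree-2 chains of the cycle-core hull.

    A component of the hull that is a bare cycle is represented by its
    lexicographically smallest vertex carrying a self-loop.  ``chains`` maps
    each contracted edge key to the original vertex sequence it replaces.
    """

    graph: nx.MultiGraph
    chains: dict[tuple[str, str, int], list[str]]

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def feedback_edge_set_size(g: nx.Graph) -> int:
    """Minimum number of edges whose removal leaves the graph acyclic."""
    return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)


def feedback_edge_set(g: nx.Graph) -> set[tuple[str, str]]:
    """An actual minimum feedback edge set (complement of a spanning forest)."""
    forest: set[frozenset] = set()
    for tree in nx.minimum_spanning_edges(g, data=False, algorithm="kruskal"):
        forest.add(frozenset(tree))
    return {tuple(sorted((u, v))) for u, v in g.edges if frozenset((u, v)) not in forest}


def fvs_upper_bound(g: nx.Graph) -> int:
    """Greedy feedback-vertex-set upper bound: peel max-degree vertices.

    Repeatedly removes a maximum-degree vertex (lexicographic tie-break)
    while a cycle remains; the removed set is verified to leave a forest.
    """
    h = g.copy()
    removed = 0
    while feedback_edge_set_size(h) > 0:
        v = max(sorted(h.nodes, key=str), key=lambda x: h.degree[x])
        h.remove_node(v)
        removed += 1
    assert nx.is_forest(h)
    return removed


def h_index(g: nx.Graph) -> int:
    """Largest h such that h vertices have degree at least h."""
    degrees = sorted((d for _, d in g.degree), reverse=True)
    h = 0
    for i, d in enumerate(degrees, start=1):
        if d >= i:
            h = i
        else:
            break
    return h


def degeneracy(g: nx.Graph) -> int:
    """Smallest d such that every subgraph has a vertex of degree <= d."""
    if g.number_of_nodes() == 0:
        return 0
    return max(nx.core_number(g).values(), default=0)


def profile(g: nx.Graph) -> GraphProfile:
    degrees = [d for _, d in g.degree]
    n = g.number_of_nodes()
    return GraphProfile(
        n_vertices=n,
        n_edges=g.number_of_edges(),
        min_degree=min(degrees) if degrees else 0,
        max_degree=max(degrees) if degrees else 0,
        avg_degree=(2 * g.number_of_edges() / n) if n else 0.0,
        fes=feedback_edge_set_size(g),
        fvs_ub=fvs_upper_bound(g),
        h_index=h_index(g),
        degeneracy=degeneracy(g),
    )


def cycle_core(g: nx.Graph) -> CycleCore:
    """Compute cycle vertices, their convex hull, and pendant trees.

    A vertex is on a cycle iff it is incident with a non-bridge edge.  The
    hull V* additionally contains every vertex on a path between two cycle
    vertices; it is obtained by repeatedly pruning degree-<=1 vertices that
    are not cycle vertices (on the tree-like bridge structure this is
    equivalent to the shortest-path characterisation).
    """
    bridges = {frozenset(e) for e in nx.bridges(g)}
    v_circle = set()
    for u, v in g.edges:
        if frozenset((u, v)) not in bridges:
            v_circle.add(u)
            v_circle.add(v)

    h = g.copy()
    pruned = True
    while pruned:
        pruned = False
        for v in sorted(h.nodes, key=str):
            if h.degree[v] <= 1 and v not in v_circle:
                h.remove_node(v)
                pruned = True
    v_star = set(h.nodes)

    pendant_trees: dict[str, set[str]] = {}
    stray: list[set[str]] = []
    rest = g.subgraph(set(g.nodes) - v_star)
    for comp in nx.connected_components(rest):
        roots = {w for u in comp for w in g.neighbors(u) if w in v_star}
        if not roots:
            stray.append(set(comp))
            continue
        assert len(roots) == 1, "a pendant tree attaches to exactly one hull vertex"
        (root,) = roots
        pendant_trees.setdefault(root, {root}).update(comp)
    return CycleCore(v_circle, v_star, pendant_trees, stray)


def contract_degree2(g: nx.Graph, v_star: set[str]) -> ContractedCore:
    """Contract maximal degree-2 chains of the hull subgraph G* into edges.

    Degrees are taken within G* = G[V*].  Pure-cycle components collapse to
    one vertex with a self-loop.  The back-map records, per contracted edge,
    the original chain as a vertex sequence including both endpoints.
    """
    gs = g.subgraph(v_star)
    core = nx.MultiGraph()
    chains: dict[tuple[str, str, int], list[str]] = {}
    keep = {v for v in gs.nodes if gs.degree[v] != 2}

    for comp in nx.connected_components(gs):
        anchors = sorted((v for v in comp if v in keep), key=str)
        if not anchors:
            # bare cycle: keep the smallest vertex, self-loop for the rest
            rep = min(comp, key=str)
            if len(comp) == 1:
                core.add_node(rep)
                continue
            seq = [rep]
            prev, cur = rep, min(gs.neighbors(rep), key=str)
            while cur != rep:
                seq.append(cur)
                nxts = [w for w in gs.neighbors(cur) if w != prev]
                prev, cur = cur, nxts[0]
            seq.append(rep)
            key = core.add_edge(rep, rep)
            chains[(rep, rep, key)] = seq
            continue
        for v in anchors:
            core.add_node(v)
        seen_chain: set[frozenset] = set()
        for v in anchors:
            for w in sorted(gs.neighbors(v), key=str):
                seq = [v, w]
                prev = v
                while w not in keep:
                    nxts = [x for x in gs.neighbors(w) if x != prev]
                    prev, w = w, nxts[0]
                    seq.append(w)
                sig = frozenset([(seq[0], seq[1]), (seq[-1], seq[-2])])
                if len(seq) > 2 and sig in seen_chain:
                    continue  # already traced from the other end
                if len(seq) == 2 and str(seq[0]) > str(seq[1]):
                    continue  # plain anchor-anchor edge, add once
                seen_chain.add(sig)
                key = core.add_edge(seq[0], seq[-1])
                chains[(seq[0], seq[-1], key)] = seq
    return ContractedCore(core, chains)


def check_core_bounds(g: nx.Graph) -> tuple[int, int, int]:
    """For a connected graph, assert |V+| <= 2 FES and |E+| <= 3 FES.

    These bounds follow from every contracted-core vertex having degree >= 3
    (so 2|E| >= 3|V|) together with |E| <= |V| + FES; they hold whenever the
    graph contains at least one cycle.  Returns (|V+|, |E+|, FES).
    """
    assert nx.is_connected(g)
    fes = feedback_edge_set_size(g)
    core = cycle_core(g)
    contracted = contract_degree2(g, core.v_star)
    nV, nE = contracted.n_vertices, contracted.n_edges
    if fes > 0:
        assert nV <= 2 * fes, (nV, fes)
        assert nE <= 3 * fes, (nE, fes)
    return nV, nE, fes
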