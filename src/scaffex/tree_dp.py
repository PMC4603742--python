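"""Dynamic program for scaffolding on trees.

When the scaffold graph is a tree, a solution can contain no cycles, so the
problem reduces to selecting a maximum-weight set of links whose union with
the contig edges decomposes the tree into exactly ``sigma_p`` alternating
paths.  The solver roots the tree and fills, bottom-up, a table

    ``[c, i, j]_v`` = maximum weight of a selection covering the subtree
    made of v and the subtrees of its first j children, forming exactly i
    paths, with exactly c in {0, 1} selected link edges incident to v,

processing the children of each vertex one at a time (a second, inner
dynamic program over the child index j).  A path here is a component of the
graph spanned by the selected links plus the contig edges *within the
subtree*; a vertex whose contig partner lies outside the processed subtree
and which is incident to no selected link spans no component yet, which is
what makes the path bookkeeping below exact.

Total work is O(n * sigma_p^2).  The table recurrences distinguish whether
the currently processed child is the contig partner of v and whether the
link between them is selected; backpointers make the optimal selection
reconstructible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .model import Cover, ScaffoldGraph, classify_selection, edge_key

NEG_INF = float("-inf")


@dataclass
class TreeDPTable:
    """Per-vertex DP tables plus the rooting used to fill them."""

    root: str
    children: dict[str, list[str]]
    parent: dict[str, Optional[str]]
    # entries[v][c][i][j] -> value (NEG_INF when infeasible)
    entries: dict[str, list[list[list[float]]]]

    def value(self, v: str, c: int, i: int, j: Optional[int] = None) -> float:
        tab = self.entries[v]
        if j is None:
            j = len(self.children[v])
        return tab[c][i][j]


@dataclass
class _BP:
    """Backpointer for one (c, i, j) entry: how child j was merged."""

    alpha: int
    ell: int
    c_prev: int
    i_prev: int
    take_edge: bool


def _root_tree(sg: ScaffoldGraph, component: set[str]):
    root = min(component)
    children: dict[str, list[str]] = {}
    parent: dict[str, Optional[str]] = {root: None}
    order = [root]
    stack = [root]
    while stack:
        v = stack.pop()
        kids = sorted(u for u in sg.graph.neighbors(v) if u != parent[v])
        children[v] = kids
        for u in kids:
            parent[u] = v
            order.append(u)
            stack.append(u)
    return root, children, parent, order


def _fill_tables(sg: ScaffoldGraph, component: set[str], sigma_p: int):
    root, children, parent, order = _root_tree(sg, component)
    entries: dict[str, list[list[list[float]]]] = {}
    bps: dict[str, list[list[list[Optional[_BP]]]]] = {}

    for v in reversed(order):  # children before parents
        kids = children[v]
        nj = len(kids)
        tab = [[[NEG_INF] * (nj + 1) for _ in range(sigma_p + 1)] for _ in range(2)]
        bp = [[[None] * (nj + 1) for _ in range(sigma_p + 1)] for _ in range(2)]
        tab[0][0][0] = 0.0
        partner = sg.partner(v)
        for j in range(1, nj + 1):
            u = kids[j - 1]
            utab = entries[u]
            nu = len(children[u])
            u_final = [[utab[a][l][nu] for l in range(sigma_p + 1)] for a in range(2)]
            is_m = sg.is_matching_edge(u, v)
            w_uv = sg.weight(u, v)
            partner_done = (not is_m) and partner in kids[:j]
            for i in range(sigma_p + 1):
                for c in (0, 1):
                    best, best_bp = NEG_INF, None

                    def consider(val, rec):
                        nonlocal best, best_bp
                        if val > best:
                            best, best_bp = val, rec

                    if is_m:
                        for alpha in (0, 1):
                            for ell in range(0, i - (1 - alpha) + 1 if c == 0 else i + 1):
                                if c == 0:
                                    ip = i - (ell - alpha + 1)
                                else:
                                    ip = i - (ell - alpha)
                                if ip < 0 or ip > sigma_p:
                                    continue
                                val = u_final[alpha][ell] + tab[c][ip][j - 1]
                                consider(val, _BP(alpha, ell, c, ip, False))
                    else:
                        if c == 0:
                            for alpha in (0, 1):
                                for ell in range(0, i + 1):
                                    val = u_final[alpha][ell] + tab[0][i - ell][j - 1]
                                    consider(val, _BP(alpha, ell, 0, i - ell, False))
                        else:
                            # uv not selected: the selected edge at v lies earlier
                            for alpha in (0, 1):
                                for ell in range(0, i + 1):
                                    val = u_final[alpha][ell] + tab[1][i - ell][j - 1]
                                    consider(val, _BP(alpha, ell, 1, i - ell, False))
                            # uv selected: u's subtree contributes ell whole paths,
                            # and the path through uv either merges with the one
                            # already containing v (contig partner processed) or
                            # merely extends to v (partner still outside)
                            for ell in range(0, i + 1):
                                ip = i - (ell - 1) if partner_done else i - ell
                                if ip < 0 or ip > sigma_p:
                                    continue
                                val = w_uv + u_final[0][ell] + tab[0][ip][j - 1]
                                consider(val, _BP(0, ell, 0, ip, True))
                    tab[c][i][j] = best
                    bp[c][i][j] = best_bp
        entries[v] = tab
        bps[v] = bp
    return TreeDPTable(root, children, parent, entries), bps


def _reconstruct(sg, table: TreeDPTable, bps, v: str, c: int, i: int) -> set:
    """Walk backpointers from (c, i, |children|)_v collecting selected links."""
    edges: set[tuple[str, str]] = set()
    stack = [(v, c, i, len(table.children[v]))]
    while stack:
        v, c, i, j = stack.pop()
        if j == 0:
            assert (c, i) == (0, 0)
            continue
        rec: _BP = bps[v][c][i][j]
        assert rec is not None
        u = table.children[v][j - 1]
        if rec.take_edge:
            edges.add(edge_key(u, v))
        stack.append((u, rec.alpha, rec.ell, len(table.children[u])))
        stack.append((v, rec.c_prev, rec.i_prev, j - 1))
    return edges


def solve_on_tree(
    sg: ScaffoldGraph, sigma_p: int
) -> tuple[Optional[int], Optional[Cover]]:
    """Optimal sigma_p-path cover of an acyclic scaffold graph.

    Returns ``(optimum_weight, cover)`` or ``(None, None)`` when no cover
    with exactly ``sigma_p`` paths exists.  Forests are handled by solving
    each tree component for every path count and combining the components
    with a small knapsack over the split of ``sigma_p``.
    """
    g = sg.graph
    if g.number_of_edges() and not nx.is_forest(g):
        raise ValueError("solve_on_tree requires an acyclic scaffold graph")
    if sigma_p < 0:
        raise ValueError("sigma_p must be non-negative")
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=min)
    if not comps:
        return (0, Cover(frozenset(), 0, 0, 0)) if sigma_p == 0 else (None, None)

    per_comp = []
    for comp in comps:
        table, bps = _fill_tables(sg, comp, sigma_p)
        r = table.root
        nj = len(table.children[r])
        best: dict[int, tuple[float, int]] = {}
        for i in range(sigma_p + 1):
            vals = [table.entries[r][c][i][nj] for c in (0, 1)]
            c = 0 if vals[0] >= vals[1] else 1
            if vals[c] > NEG_INF:
                best[i] = (vals[c], c)
        per_comp.append((table, bps, best))

    # knapsack over components: exact split of sigma_p
    state: dict[int, tuple[float, tuple[int, ...]]] = {0: (0.0, ())}
    for _, _, best in per_comp:
        new_state: dict[int, tuple[float, tuple[int, ...]]] = {}
        for used, (w0, picks) in state.items():
            for i, (w, _) in best.items():
                tot = used + i
                if tot > sigma_p:
                    continue
                cand = (w0 + w, picks + (i,))
                if tot not in new_state or cand[0] > new_state[tot][0]:
                    new_state[tot] = cand
        state = new_state
    if sigma_p not in state:
        return None, None
    total, picks = state[sigma_p]
    edges: set[tuple[str, str]] = set()
    for (table, bps, best), i in zip(per_comp, picks):
        _, c = best[i]
        edges |= _reconstruct(sg, table, bps, table.root, c, i)
    cover = classify_selection(sg, edges)
    assert cover.n_paths == sigma_p and cover.n_cycles == 0
    assert cover.weight == int(total)
    return int(total), cover


def dump_table(sg: ScaffoldGraph, sigma_p: int) -> TreeDPTable:
    """Fill and return the DP table of a connected tree (for inspection)."""
    g = sg.graph
    if not (nx.is_forest(g) and nx.is_connected(g)):
        raise ValueError("dump_table requires a connected tree")
    table, _ = _fill_tables(sg, set(g.nodes), sigma_p)
    return table
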