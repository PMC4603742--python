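"""Treewidth-parameterized dynamic program for scaffolding.

The solver runs over a nice tree decomposition of the scaffold graph.  For
every bag it tabulates partial solutions by how they interact with the bag:

* ``d``: the degree (0, 1 or 2) of each bag vertex in the graph spanned by
  the selected links plus the contig edges introduced so far,
* ``P``: an involution (a matching allowing fixed points) on the degree-1
  bag vertices -- a pair (u, v) records a partial path connecting u and v,
  a fixed point (u, u) records a path dangling from u whose other end has
  already been forgotten,
* ``p``/``c``: counts of completed paths/cycles avoiding all degree-1 bag
  vertices.

A table entry stores the maximum total link weight over all edge selections
realising that interaction.  Contig (matching) edges are forced into the
solution at their introduce-edge bag and contribute no weight; link edges
take the better of inclusion (adding their weight) and exclusion.  Join
bags compose the two children's involutions by tracing the maximal
alternating chains of their union; chains that close into cycles or into
paths avoiding the bag move into the ``c``/``p`` counters.  The optimum is
read from the empty root bag at the exact target counts and a witness
cover is rebuilt from backpointers.

The number of involutions per bag is roughly (tw+2)^(tw+1), so a
configurable width cap refuses decompositions for which the blow-up would
be unreasonable.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx

from .decomposition import NiceTreeDecomposition, greedy_fillin, make_nice
from .model import Cover, ScaffoldGraph, classify_selection, edge_key

# state: (degrees aligned with the node's sorted bag, involution pairs, p, c)
State = tuple[tuple[int, ...], tuple[tuple[str, str], ...], int, int]

DEFAULT_WIDTH_CAP = 12


class WidthCapExceeded(RuntimeError):
    """The decomposition is wider than the configured safety cap."""


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _canon_P(pairs) -> tuple[tuple[str, str], ...]:
    return tuple(sorted(_key(a, b) for a, b in pairs))


def _pmap(P) -> dict[str, str]:
    m: dict[str, str] = {}
    for a, b in P:
        m[a], m[b] = b, a
    return m


def _compose(P1, P2) -> tuple[tuple[tuple[str, str], ...], int, int]:
    """Glue two involutions at a join bag.

    Treat every pair as a path segment (a fixed point is a segment with one
    free end reaching past the bag) and trace the maximal chains of the
    union, alternating sides.  A chain end is *open* at a vertex paired on
    exactly one side (it remains in the joint involution) and *free* at a
    shared fixed point.  Open/open chains become pairs, open/free chains
    fixed points, free/free chains completed paths avoiding the bag, and
    closed chains completed cycles.  Returns (P, #paths, #cycles).
    """
    dom = ({v for pr in P1 for v in pr}, {v for pr in P2 for v in pr})
    pm = (_pmap(P1), _pmap(P2))
    visited: set[tuple[int, tuple[str, str]]] = set()
    pairs: list[tuple[str, str]] = []
    n_paths = n_cycles = 0

    def walk(v: str, s: int):
        """Extend a chain from vertex v onto side s until it ends."""
        while True:
            if v not in dom[s]:
                return ("open", v)
            seg = (s, _key(v, pm[s][v]))
            if seg in visited:
                return ("cycle", None)
            visited.add(seg)
            w = pm[s][v]
            if w == v:
                return ("free", None)
            v, s = w, 1 - s

    for s0, P in ((0, P1), (1, P2)):
        for pr in sorted(P):
            a, b = _key(*pr)
            if (s0, (a, b)) in visited:
                continue
            visited.add((s0, (a, b)))
            if a == b:
                e1 = ("free", None)
                e2 = walk(a, 1 - s0)
            else:
                e1 = walk(a, 1 - s0)
                e2 = walk(b, 1 - s0) if e1[0] != "cycle" else ("cycle", None)
            kinds = {e1[0], e2[0]}
            if "cycle" in kinds:
                n_cycles += 1
            elif kinds == {"free"}:
                n_paths += 1
            elif kinds == {"open"}:
                pairs.append(_key(e1[1], e2[1]))
            else:  # one open, one free: a dangling path
                v = e1[1] if e1[0] == "open" else e2[1]
                pairs.append((v, v))
    return _canon_P(pairs), n_paths, n_cycles


def _include_edge(
    dmap: dict[str, int],
    P,
    p: int,
    c: int,
    u: str,
    v: str,
    max_p: int,
    max_c: int,
):
    """State after adding edge uv to the selection, or None if impossible."""
    du, dv = dmap[u], dmap[v]
    if du >= 2 or dv >= 2:
        return None
    pm = _pmap(P)
    newP = set(P)
    np_, nc_ = p, c
    if du == 1 and dv == 1:
        pu, pv = pm[u], pm[v]
        if pu == v:  # the partial u-v path closes into a cycle
            newP.discard(_key(u, v))
            nc_ += 1
        elif pu == u and pv == v:  # two dangling paths merge, avoiding the bag
            newP.discard((u, u))
            newP.discard((v, v))
            np_ += 1
        elif pu == u:  # dangling at u + v..pv path -> dangling at pv
            newP.discard((u, u))
            newP.discard(_key(v, pv))
            newP.add((pv, pv))
        elif pv == v:
            newP.discard((v, v))
            newP.discard(_key(u, pu))
            newP.add((pu, pu))
        else:  # pu..u + v..pv -> pu..pv
            newP.discard(_key(u, pu))
            newP.discard(_key(v, pv))
            newP.add(_key(pu, pv))
    elif du == 1 or dv == 1:
        x, y = (u, v) if du == 1 else (v, u)  # x paired, y fresh
        px = pm[x]
        if px == x:
            newP.discard((x, x))
            newP.add((y, y))
        else:
            newP.discard(_key(x, px))
            newP.add(_key(y, px))
    else:  # both fresh: the edge itself is a new partial path
        newP.add(_key(u, v))
    if np_ > max_p or nc_ > max_c:
        return None
    nd = dict(dmap)
    nd[u], nd[v] = du + 1, dv + 1
    return nd, _canon_P(newP), np_, nc_


def _pack(bag: tuple[str, ...], dmap: dict[str, int], P, p: int, c: int) -> State:
    return (tuple(dmap[v] for v in bag), P, p, c)


def _unpack(bag: tuple[str, ...], state: State):
    degs, P, p, c = state
    return dict(zip(bag, degs)), P, p, c


def compute_tables(
    sg: ScaffoldGraph,
    nd: NiceTreeDecomposition,
    max_p: int,
    max_c: int,
    max_width: Optional[int] = DEFAULT_WIDTH_CAP,
):
    """Fill the DP tables bottom-up; returns (tables, backpointers)."""
    if max_width is not None and nd.width > max_width:
        raise WidthCapExceeded(
            f"decomposition width {nd.width} exceeds cap {max_width}"
        )
    tables: list[dict[State, int]] = [dict() for _ in nd.nodes]
    back: list[dict[State, tuple]] = [dict() for _ in nd.nodes]

    for node in nd.nodes:  # children precede parents by construction
        tab = tables[node.id]
        bp = back[node.id]

        def put(state: State, value: int, pointer: tuple) -> None:
            if state not in tab or value > tab[state]:
                tab[state] = value
                bp[state] = pointer

        if node.kind == "leaf":
            put(((), (), 0, 0), 0, ((), None))
        elif node.kind == "introduce_vertex":
            (j,) = node.children
            cbag = nd.nodes[j].bag
            for cs, val in sorted(tables[j].items()):
                dmap, P, p, c = _unpack(cbag, cs)
                dmap[node.vertex] = 0
                put(_pack(node.bag, dmap, P, p, c), val, ((cs,), None))
        elif node.kind == "forget":
            (j,) = node.children
            cbag = nd.nodes[j].bag
            v = node.vertex
            for cs, val in sorted(tables[j].items()):
                dmap, P, p, c = _unpack(cbag, cs)
                dv = dmap.pop(v)
                if dv in (0, 2):
                    put(_pack(node.bag, dmap, P, p, c), val, ((cs,), None))
                else:
                    pm = _pmap(P)
                    pv = pm[v]
                    if pv == v:  # the dangling path is now a completed path
                        if p + 1 <= max_p:
                            newP = _canon_P(set(P) - {(v, v)})
                            put(_pack(node.bag, dmap, newP, p + 1, c), val, ((cs,), None))
                    else:  # the partial path keeps dangling from its other end
                        newP = _canon_P((set(P) - {_key(v, pv)}) | {(pv, pv)})
                        put(_pack(node.bag, dmap, newP, p, c), val, ((cs,), None))
        elif node.kind == "introduce_edge":
            (j,) = node.children
            cbag = nd.nodes[j].bag
            u, v = node.edge
            is_m = sg.is_matching_edge(u, v)
            w = 0 if is_m else sg.weight(u, v)
            for cs, val in sorted(tables[j].items()):
                dmap, P, p, c = _unpack(cbag, cs)
                if not is_m:  # links may be skipped; contig edges may not
                    put(_pack(node.bag, dmap, P, p, c), val, ((cs,), None))
                res = _include_edge(dmap, P, p, c, u, v, max_p, max_c)
                if res is not None:
                    nd_, nP, np_, nc_ = res
                    put(_pack(node.bag, nd_, nP, np_, nc_), val + w, ((cs,), node.edge))
        elif node.kind == "join":
            j, l = node.children
            bag = node.bag
            for cs1, val1 in sorted(tables[j].items()):
                d1, P1, p1, c1 = _unpack(bag, cs1)
                for cs2, val2 in sorted(tables[l].items()):
                    d2, P2, p2, c2 = _unpack(bag, cs2)
                    dmap = {}
                    ok = True
                    for x in bag:
                        s = d1[x] + d2[x]
                        if s > 2:
                            ok = False
                            break
                        dmap[x] = s
                    if not ok:
                        continue
                    P, dp, dc = _compose(P1, P2)
                    p, c = p1 + p2 + dp, c1 + c2 + dc
                    if p > max_p or c > max_c:
                        continue
                    put(_pack(bag, dmap, P, p, c), val1 + val2, ((cs1, cs2), None))
        else:  # pragma: no cover
            raise AssertionError(node.kind)

        # resource guard: involutions per bag are bounded in the width
        n_P = len({s[1] for s in tab})
        k = len(node.bag)
        assert n_P <= max(1, (k + 2) ** (k + 1))
    return tables, back


def _reconstruct(nd: NiceTreeDecomposition, back, root_state: State) -> set:
    edges: set[tuple[str, str]] = set()
    stack = [(nd.root, root_state)]
    while stack:
        nid, state = stack.pop()
        children_states, edge = back[nid][state]
        if edge is not None:
            edges.add(edge_key(*edge))
        for cid, cs in zip(nd.nodes[nid].children, children_states):
            stack.append((cid, cs))
    return edges


def solve_tw_all(
    sg: ScaffoldGraph,
    sigma_p: int,
    sigma_c: int,
    nice_dec: Optional[NiceTreeDecomposition] = None,
    max_width: Optional[int] = DEFAULT_WIDTH_CAP,
) -> dict[tuple[int, int], tuple[int, Cover]]:
    """Optima for *all* path/cycle counts up to (sigma_p, sigma_c) in one run.

    Returns a map (p, c) -> (optimum weight, witness cover) containing only
    the feasible count combinations.
    """
    if nice_dec is None:
        nice_dec = make_nice(greedy_fillin(sg.graph), sg.graph)
    tables, back = compute_tables(sg, nice_dec, sigma_p, sigma_c, max_width)
    root_tab = tables[nice_dec.root]
    out: dict[tuple[int, int], tuple[int, Cover]] = {}
    matching = sg.matching
    for (degs, P, p, c), val in sorted(root_tab.items()):
        assert degs == () and P == ()
        edges = _reconstruct(nice_dec, back, ((), (), p, c))
        cover = classify_selection(sg, edges - matching)
        assert cover.n_paths == p and cover.n_cycles == c, (cover, p, c)
        assert cover.weight == val
        out[(p, c)] = (val, cover)
    return out


def solve_tw(
    sg: ScaffoldGraph,
    sigma_p: int,
    sigma_c: int,
    nice_dec: Optional[NiceTreeDecomposition] = None,
    max_width: Optional[int] = DEFAULT_WIDTH_CAP,
) -> tuple[Optional[int], Optional[Cover]]:
    """Maximum-weight cover with exactly sigma_p paths and sigma_c cycles.

    Returns ``(None, None)`` when no such cover exists.
    """
    res = solve_tw_all(sg, sigma_p, sigma_c, nice_dec, max_width)
    if (sigma_p, sigma_c) not in res:
        return None, None
    return res[(sigma_p, sigma_c)]


def solve_at_most(
    sg: ScaffoldGraph,
    sigma_p: int,
    sigma_c: int,
    nice_dec: Optional[NiceTreeDecomposition] = None,
    max_width: Optional[int] = DEFAULT_WIDTH_CAP,
) -> tuple[Optional[int], Optional[Cover]]:
    """Best cover over all counts (p <= sigma_p, c <= sigma_c)."""
    res = solve_tw_all(sg, sigma_p, sigma_c, nice_dec, max_width)
    best: tuple[Optional[int], Optional[Cover]] = (None, None)
    for (p, c), (val, cover) in sorted(res.items()):
        if best[0] is None or val > best[0]:
            best = (val, cover)
    return best
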