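"""Seeded synthetic scaffold-graph generators.

Real scaffold graphs are sparse, tree-like structures: contigs linked by a
noisy web of paired-end evidence whose independent-cycle count (FES) is
small compared to the vertex count.  The generators here emulate the input
classes the solvers target -- trees, bounded-FES sparse graphs, instances
with a planted unique optimum, and reducible restricted instances built
from planted fixed-length paths and cycles -- without requiring any
external data.  Every generator is a pure function of its arguments: the
same seed yields a byte-identical instance.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .kernel import RSCAInstance
from .model import Cover, ScaffoldGraph, edge_key

WeightRange = tuple[int, int]


def _rng(seed: int) -> random.Random:
    return random.Random(seed)


def _vname(i: int) -> str:
    return f"v{i:04d}"


def gen_tree_instance(
    n_contigs: int, seed: int, weight_range: WeightRange = (1, 20)
) -> ScaffoldGraph:
    """A random tree on 2*n_contigs vertices whose matching edges are tree edges.

    Contigs are attached one by one to a uniformly chosen existing vertex,
    emulating a fully resolved (cycle-free) link structure.  Matching edges
    have weight 0; links draw uniformly from ``weight_range``.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    lo, hi = weight_range
    rng = _rng(seed)
    sg = ScaffoldGraph()
    sg.add_edge(_vname(0), _vname(1), weight=0, matching=True)
    for i in range(1, n_contigs):
        a, b = _vname(2 * i), _vname(2 * i + 1)
        sg.add_edge(a, b, weight=0, matching=True)
        host = rng.choice(sorted(sg.vertices[: 2 * i]))
        end = rng.choice([a, b])
        sg.add_edge(host, end, weight=rng.randint(lo, hi), matching=False)
    return sg


def gen_bounded_tw_instance(
    n_contigs: int,
    max_extra_edges: int,
    seed: int,
    weight_range: WeightRange = (1, 20),
) -> ScaffoldGraph:
    """A sparse instance: a random tree plus up to ``max_extra_edges`` links.

    The feedback edge set of the result is at most ``max_extra_edges``.
    With 17 contigs and 10 extra links this reproduces the dimensions of a
    small viral-genome scaffold graph (34 vertices, 43 edges).
    """
    rng = _rng(seed)
    sg = gen_tree_instance(n_contigs, rng.randrange(2**31), weight_range)
    lo, hi = weight_range
    verts = sg.vertices
    attempts = 0
    added = 0
    while added < max_extra_edges and attempts < 50 * max_extra_edges + 50:
        attempts += 1
        u, v = rng.sample(verts, 2)
        if sg.has_edge(u, v):
            continue
        sg.add_edge(u, v, weight=rng.randint(lo, hi), matching=False)
        added += 1
    return sg


def gen_planted_instance(
    sigma_p: int,
    sigma_c: int,
    path_len: int = 3,
    cycle_len: int = 4,
    n_decoys: int = 10,
    decoy_max_weight: int = 5,
    planted_weight: Optional[int] = None,
    seed: int = 0,
    acyclic: bool = False,
) -> tuple[ScaffoldGraph, Cover]:
    """Plant a sigma_p/sigma_c cover that is provably the unique optimum.

    The planted cover consists of ``sigma_p`` alternating paths of
    ``path_len`` edges (odd) and ``sigma_c`` alternating cycles of
    ``cycle_len`` edges (even, >= 4).  Decoy links of weight at most
    ``decoy_max_weight`` are then added; every planted link weighs strictly
    more than any decoy, and since every cover with the same component
    counts selects exactly |M| - sigma_p links, swapping any planted link
    for a decoy strictly loses weight -- so the plant is the unique optimum.

    With ``acyclic=True`` decoys are only added where they close no cycle,
    keeping the instance a forest (usable by the tree solver; requires
    ``sigma_c == 0``).
    """
    if path_len % 2 == 0:
        raise ValueError("path_len must be odd (alternating paths)")
    if cycle_len % 2 or cycle_len < 4:
        raise ValueError("cycle_len must be even and >= 4")
    if acyclic and sigma_c > 0:
        raise ValueError("acyclic planting cannot contain cycles")
    rng = _rng(seed)
    sg = ScaffoldGraph()
    planted: list[tuple[str, str]] = []
    idx = 0

    def fresh() -> str:
        nonlocal idx
        idx += 1
        return _vname(idx - 1)

    for _ in range(sigma_p):
        verts = [fresh() for _ in range(path_len + 1)]
        for i in range(path_len):
            sg.add_edge(verts[i], verts[i + 1], weight=0, matching=(i % 2 == 0))
            if i % 2 == 1:
                planted.append(edge_key(verts[i], verts[i + 1]))
    for _ in range(sigma_c):
        verts = [fresh() for _ in range(cycle_len)]
        for i in range(cycle_len):
            u, v = verts[i], verts[(i + 1) % cycle_len]
            sg.add_edge(u, v, weight=0, matching=(i % 2 == 0))
            if i % 2 == 1:
                planted.append(edge_key(u, v))

    n_s = len(planted)
    if planted_weight is None:
        planted_weight = n_s * (decoy_max_weight + 10)
    if n_s:
        base, extra = divmod(planted_weight, n_s)
        if base <= decoy_max_weight:
            raise ValueError("planted_weight too small for strict decoy dominance")
        for j, (u, v) in enumerate(sorted(planted)):
            sg.set_weight(u, v, base + (1 if j < extra else 0))
    elif planted_weight:
        raise ValueError("no planted links to carry planted_weight")

    verts = sg.vertices
    added = attempts = 0
    while added < n_decoys and attempts < 50 * n_decoys + 50:
        attempts += 1
        u, v = rng.sample(verts, 2)
        if sg.has_edge(u, v):
            continue
        if acyclic and nx.has_path(sg.graph, u, v):
            continue
        sg.add_edge(u, v, weight=rng.randint(0, decoy_max_weight), matching=False)
        added += 1

    cover = Cover(frozenset(planted), sigma_p, sigma_c, planted_weight)
    return sg, cover


def gen_rsca_instance(
    sigma_p: int,
    sigma_c: int,
    ell_p: int,
    ell_c: int,
    n_pendants: int = 0,
    n_subdivisions: int = 0,
    seed: int = 0,
    weight_range: WeightRange = (1, 20),
) -> RSCAInstance:
    """A reducible yes-instance of the restricted (fixed-lengths) problem.

    The planted solution consists of ``sigma_p`` alternating paths of
    exactly ``ell_p`` edges (odd) and ``sigma_c`` alternating cycles of
    exactly ``ell_c`` edges.  The instance is then obfuscated while keeping
    the plant feasible:

    * ``n_subdivisions`` planted paths are absorbed into long cycles built
      from chained path blocks (covered by deleting the chaining links),
      creating long degree-2 chains for the path reduction rules;
    * ``n_pendants`` planted paths are hung as pendant block-chains off
      cycle vertices (covered by deleting the connector links), creating
      pendant trees for the tree reduction rules;
    * remaining planted paths are chained into isolated long paths.

    ``k`` is set to the weight kept by the planted solution, so the result
    is a yes-instance by construction.
    """
    if ell_p % 2 == 0 or ell_p < 1:
        raise ValueError("ell_p must be odd and positive")
    if ell_c % 2 or ell_c < 4:
        raise ValueError("ell_c must be even and >= 4 (alternating cycles)")
    rng = _rng(seed)
    lo, hi = weight_range
    sg = ScaffoldGraph()
    idx = 0

    def fresh() -> str:
        nonlocal idx
        idx += 1
        return _vname(idx - 1)

    kept_weight = 0

    def new_block() -> tuple[list[str], int]:
        """An isolated alternating path of ell_p edges; returns (vertices, kept w)."""
        nonlocal kept_weight
        verts = [fresh() for _ in range(ell_p + 1)]
        for i in range(ell_p):
            w = 0 if i % 2 == 0 else rng.randint(lo, hi)
            sg.add_edge(verts[i], verts[i + 1], weight=w, matching=(i % 2 == 0))
            kept_weight += w
        return verts, 0

    cycle_hosts: list[str] = []  # cycle vertices able to host a pendant

    for _ in range(sigma_c):
        verts = [fresh() for _ in range(ell_c)]
        for i in range(ell_c):
            u, v = verts[i], verts[(i + 1) % ell_c]
            w = 0 if i % 2 == 0 else rng.randint(lo, hi)
            sg.add_edge(u, v, weight=w, matching=(i % 2 == 0))
            kept_weight += w
        cycle_hosts.extend(verts)

    n_subdivisions = min(n_subdivisions, max(0, sigma_p - n_pendants))
    n_pendants = min(n_pendants, sigma_p - n_subdivisions)

    # long cycles: groups of >= 2 blocks closed into a cycle by connector
    # links; a block may be "bent" at position s, laying only its suffix
    # along the cycle and leaving its prefix as a short pendant (< ell_p)
    # rooted on the chain -- the solution path simply turns the corner
    remaining = n_subdivisions
    while remaining >= 2:
        group = min(remaining, rng.randint(2, 4))
        entries = []
        for _ in range(group):
            block, _ = new_block()
            s = 0
            if ell_p >= 3 and rng.random() < 0.4:
                s = rng.randint(1, ell_p - 1)
            entries.append((block[s], block[-1]))
            cycle_hosts.extend(block)
        for j, (_, exit_v) in enumerate(entries):
            entry_next = entries[(j + 1) % group][0]
            sg.add_edge(exit_v, entry_next, weight=rng.randint(lo, hi), matching=False)
        remaining -= group
    in_cycles = n_subdivisions - remaining  # a leftover group of 1 stays plain

    # pendant chains: blocks hung off cycle vertices via connector links
    pend_left = n_pendants if cycle_hosts else 0
    n_plain = sigma_p - in_cycles - pend_left
    while pend_left > 0:
        t = min(pend_left, rng.randint(1, 2))
        host = rng.choice(sorted(set(cycle_hosts)))
        for _ in range(t):
            block, _ = new_block()
            sg.add_edge(host, block[0], weight=rng.randint(lo, hi), matching=False)
            host = block[-1]
        pend_left -= t

    # isolated long paths: chains of blocks joined by connector links
    plain_left = n_plain
    while plain_left > 0:
        t = min(plain_left, rng.randint(1, 3))
        prev = None
        for _ in range(t):
            block, _ = new_block()
            if prev is not None:
                sg.add_edge(prev, block[0], weight=rng.randint(lo, hi), matching=False)
            prev = block[-1]
        plain_left -= t

    return RSCAInstance(sg, sigma_p, sigma_c, ell_p, ell_c, kept_weight)


def gen_connected_graph(n_vertices: int, n_edges: int, seed: int) -> nx.Graph:
    """A connected simple graph with exactly the requested dimensions."""
    if n_edges < n_vertices - 1:
        raise ValueError("too few edges for a connected graph")
    if n_edges > n_vertices * (n_vertices - 1) // 2:
        raise ValueError("too many edges for a simple graph")
    rng = _rng(seed)
    g = nx.Graph()
    names = [_vname(i) for i in range(n_vertices)]
    g.add_node(names[0])
    for v in names[1:]:
        g.add_edge(v, rng.choice(sorted(g.nodes)))
    while g.number_of_edges() < n_edges:
        u, v = rng.sample(names, 2)
        if not g.has_edge(u, v):
            g.add_edge(u, v)
    return g
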