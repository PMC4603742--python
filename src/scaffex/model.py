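"""Scaffold-graph data model and cover semantics.

A *scaffold graph* encodes the contig-ordering problem that arises after
genome assembly: every assembled contig is a pair of vertices (its two
extremities) joined by a *matching edge*, and every other edge (a *link*)
carries a non-negative integer confidence weight that the two incident
contig extremities are adjacent in the genome.  The matching edges form a
perfect matching M on the graph.

A solution is a *cover*: a matching S among the links such that the graph
spanned by S together with M decomposes into alternating paths and cycles
-- the linear and circular chromosomes of the proposed scaffolding.  Because
M is perfect and entirely kept, every such component is automatically
alternating (each vertex travels with its matching partner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

Edge = tuple[str, str]


def edge_key(u: str, v: str) -> Edge:
    """Canonical (sorted) form of an undirected edge."""
    return (u, v) if u <= v else (v, u)


class CoverError(ValueError):
    """Raised when an edge selection is not a valid cover."""


class ScaffoldGraph:
    """Weighted undirected graph with a distinguished perfect matching.

    Vertices are opaque strings; edges carry an integer ``weight`` and a
    boolean ``matching`` flag.  Iteration orders are lexicographic so that
    all downstream algorithms are deterministic.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, int, bool]]) -> "ScaffoldGraph":
        sg = cls()
        for u, v, w, m in edges:
            sg.add_edge(u, v, weight=w, matching=m)
        return sg

    def add_vertex(self, v: str) -> None:
        self._g.add_node(str(v))

    def add_edge(self, u: str, v: str, weight: int = 0, matching: bool = False) -> None:
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop {u!r} not allowed")
        if self._g.has_edge(u, v):
            raise ValueError(f"duplicate edge {u!r}-{v!r}")
        self._g.add_edge(u, v, weight=int(weight), matching=bool(matching))

    def remove_edge(self, u: str, v: str) -> None:
        self._g.remove_edge(u, v)

    def remove_vertex(self, v: str) -> None:
        self._g.remove_node(v)

    def copy(self) -> "ScaffoldGraph":
        sg = ScaffoldGraph()
        sg._g = self._g.copy()
        return sg

    # -- accessors -----------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying networkx graph (shared, mutate with care)."""
        return self._g

    @property
    def vertices(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    def edges(self) -> list[tuple[str, str, int, bool]]:
        out = []
        for u, v, data in self._g.edges(data=True):
            u, v = edge_key(u, v)
            out.append((u, v, data["weight"], data["matching"]))
        out.sort()
        return out

    @property
    def matching(self) -> set[Edge]:
        return {
            edge_key(u, v)
            for u, v, data in self._g.edges(data=True)
            if data["matching"]
        }

    @property
    def links(self) -> set[Edge]:
        return {
            edge_key(u, v)
            for u, v, data in self._g.edges(data=True)
            if not data["matching"]
        }

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def weight(self, u: str, v: str) -> int:
        return self._g.edges[u, v]["weight"]

    def set_weight(self, u: str, v: str, w: int) -> None:
        self._g.edges[u, v]["weight"] = int(w)

    def is_matching_edge(self, u: str, v: str) -> bool:
        return bool(self._g.edges[u, v]["matching"])

    def partner(self, v: str) -> Optional[str]:
        """The vertex matched with ``v``, or None if v is unmatched."""
        for u in self._g.neighbors(v):
            if self._g.edges[v, u]["matching"]:
                return u
        return None

    def degree(self, v: str) -> int:
        return self._g.degree[v]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScaffoldGraph):
            return NotImplemented
        return set(self.vertices) == set(other.vertices) and self.edges() == other.edges()

    def __repr__(self) -> str:
        return (
            f"ScaffoldGraph(n={self._g.number_of_nodes()}, "
            f"m={self._g.number_of_edges()}, contigs={len(self.matching)})"
        )


@dataclass(frozen=True)
class SolveParams:
    """Problem parameters: exact path/cycle counts and a weight threshold.

    ``sigma_p`` and ``sigma_c`` are the numbers of linear and circular
    chromosomes sought; ``k`` is an optional decision threshold (solvers
    return the optimum, the decision is derived from it).
    """

    sigma_p: int
    sigma_c: int
    k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sigma_p < 0 or self.sigma_c < 0:
            raise ValueError("sigma_p and sigma_c must be non-negative")
        if self.k is not None and self.k < 0:
            raise ValueError("k must be non-negative")


@dataclass(frozen=True)
class Cover:
    """A selection S of links whose union with M decomposes into paths/cycles."""

    edges: frozenset[Edge]
    n_paths: int
    n_cycles: int
    weight: int

    def __repr__(self) -> str:
        return (
            f"Cover(paths={self.n_paths}, cycles={self.n_cycles}, "
            f"weight={self.weight}, |S|={len(self.edges)})"
        )


def validate_scaffold_graph(sg: ScaffoldGraph) -> list[str]:
    """Check the scaffold-graph invariants; return a list of violations.

    An empty list means the graph is valid: even vertex count, the flagged
    edges form a perfect matching, and all weights are non-negative integers.
    """
    violations: list[str] = []
    g = sg.graph
    if g.number_of_nodes() % 2 != 0:
        violations.append(f"odd vertex count ({g.number_of_nodes()})")
    match_deg: dict[str, int] = {v: 0 for v in g.nodes}
    for u, v, data in g.edges(data=True):
        w = data.get("weight")
        if not isinstance(w, int) or isinstance(w, bool) or w < 0:
            violations.append(f"edge {u}-{v} has invalid weight {w!r}")
        if data.get("matching"):
            match_deg[u] += 1
            match_deg[v] += 1
    for v in sorted(match_deg):
        if match_deg[v] == 0:
            violations.append(f"unmatched vertex {v}")
        elif match_deg[v] > 1:
            violations.append(f"vertex {v} matched {match_deg[v]} times")
    return violations


def _selection_components(
    sg: ScaffoldGraph, S: Iterable[Edge]
) -> Iterator[tuple[set[str], bool]]:
    """Components of Gr(S ∪ M) as (vertex set, is_cycle) pairs."""
    h = nx.Graph()
    for u, v in sg.matching:
        h.add_edge(u, v)
    for u, v in S:
        h.add_edge(u, v)
    for comp in nx.connected_components(h):
        is_cycle = all(h.degree[x] == 2 for x in comp)
        yield comp, is_cycle


def classify_selection(sg: ScaffoldGraph, S: Iterable[Edge]) -> Cover:
    """Classify an edge selection as a cover, or raise :class:`CoverError`.

    ``S`` must consist of non-matching edges and be a matching in G - M.
    With a perfect matching kept in full, every component of Gr(S ∪ M) is
    then automatically an alternating path or cycle; the component counts
    and the total link weight define the returned :class:`Cover`.
    """
    matching = sg.matching
    S = {edge_key(u, v) for u, v in S}
    deg: dict[str, int] = {}
    total = 0
    for u, v in sorted(S):
        if not sg.has_edge(u, v):
            raise CoverError(f"edge {u}-{v} is not in the graph")
        if (u, v) in matching:
            raise CoverError(f"edge {u}-{v} is a matching edge")
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
        total += sg.weight(u, v)
    for x in sorted(deg):
        if deg[x] > 1:
            raise CoverError(f"vertex {x} is incident with {deg[x]} selected edges")
    n_paths = n_cycles = 0
    seen: set[str] = set()
    for comp, is_cycle in _selection_components(sg, S):
        # alternation is automatic: every component carries its vertices'
        # matching partners, since M is perfect and fully kept
        assert all(sg.partner(x) in comp for x in comp)
        seen |= comp
        if is_cycle:
            n_cycles += 1
        else:
            n_paths += 1
    assert seen == set(sg.graph.nodes), "perfect matching must cover all vertices"
    return Cover(frozenset(S), n_paths, n_cycles, total)


def is_solution(sg: ScaffoldGraph, params: SolveParams, S: Iterable[Edge]) -> bool:
    """True iff S is a sigma_p/sigma_c cover of weight at least k."""
    try:
        cover = classify_selection(sg, S)
    except CoverError:
        return False
    if cover.n_paths != params.sigma_p or cover.n_cycles != params.sigma_c:
        return False
    return params.k is None or cover.weight >= params.k
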