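"""Reading and writing scaffold-graph instances.

The native format is SGF ("scaffold graph format"), a small line-oriented
plain-text format:

* ``#`` starts a comment line,
* ``P <sigma_p> <sigma_c> <k>`` optionally records solve parameters,
* ``R <ell_p> <ell_c>`` optionally records restricted path/cycle lengths,
* ``E <u> <v> <weight> <matching_flag>`` records an edge; the flag is 1 for
  contig (matching) edges and 0 for links.

Vertex names are arbitrary non-whitespace tokens.  Written files are
canonical: a header comment, the P/R lines if set, then edge lines sorted by
endpoints, so write -> read round-trips bit-exactly.  DOT (export only, bold
matching edges) and GraphML (attribute-preserving round trip) are supported
for interoperability with standard graph tooling.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, TextIO, Union

import networkx as nx

from .model import ScaffoldGraph, SolveParams, edge_key, validate_scaffold_graph

PathLike = Union[str, Path]


@dataclass
class InstanceFile:
    """A scaffold graph with optional solve parameters attached."""

    graph: ScaffoldGraph
    params: Optional[SolveParams] = None
    rsca_params: Optional[tuple[int, int]] = None  # (ell_p, ell_c)


class SGFParseError(ValueError):
    pass


def _open(path_or_stream, mode: str):
    if isinstance(path_or_stream, (str, Path)):
        return open(path_or_stream, mode, encoding="utf-8"), True
    return path_or_stream, False


def read_sgf(path_or_stream: Union[PathLike, TextIO]) -> InstanceFile:
    """Parse an SGF file; raises on syntax or scaffold-invariant violations."""
    fh, close = _open(path_or_stream, "r")
    try:
        graph = ScaffoldGraph()
        params = None
        rsca = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            tag = tokens[0]
            try:
                if tag == "P":
                    sp, sc, k = map(int, tokens[1:4])
                    params = SolveParams(sp, sc, k)
                elif tag == "R":
                    lp, lc = map(int, tokens[1:3])
                    rsca = (lp, lc)
                elif tag == "E":
                    u, v = tokens[1], tokens[2]
                    w, flag = int(tokens[3]), int(tokens[4])
                    if flag not in (0, 1):
                        raise ValueError(f"matching flag must be 0/1, got {flag}")
                    graph.add_edge(u, v, weight=w, matching=bool(flag))
                else:
                    raise ValueError(f"unknown record type {tag!r}")
            except (IndexError, ValueError) as exc:
                raise SGFParseError(f"line {lineno}: {exc}") from exc
        violations = validate_scaffold_graph(graph)
        if violations:
            raise SGFParseError("invalid scaffold graph: " + "; ".join(violations))
        return InstanceFile(graph, params, rsca)
    finally:
        if close:
            fh.close()


def write_sgf(instance: InstanceFile, path_or_stream: Union[PathLike, TextIO]) -> None:
    """Write an instance in canonical SGF form."""
    fh, close = _open(path_or_stream, "w")
    try:
        sg = instance.graph
        fh.write(
            f"# scaffold graph: {sg.n_vertices} vertices, "
            f"{len(sg.matching)} contigs, {len(sg.links)} links\n"
        )
        if instance.params is not None:
            p = instance.params
            fh.write(f"P {p.sigma_p} {p.sigma_c} {p.k if p.k is not None else 0}\n")
        if instance.rsca_params is not None:
            lp, lc = instance.rsca_params
            fh.write(f"R {lp} {lc}\n")
        for u, v, w, m in sg.edges():
            fh.write(f"E {u} {v} {w} {1 if m else 0}\n")
    finally:
        if close:
            fh.close()


def sgf_string(instance: InstanceFile) -> str:
    buf = _io.StringIO()
    write_sgf(instance, buf)
    return buf.getvalue()


def export_dot(instance: InstanceFile, path_or_stream: Union[PathLike, TextIO]) -> None:
    """Write a Graphviz DOT rendering; matching (contig) edges are bold."""
    fh, close = _open(path_or_stream, "w")
    try:
        fh.write("graph scaffold {\n")
        for v in instance.graph.vertices:
            fh.write(f'  "{v}";\n')
        for u, v, w, m in instance.graph.edges():
            style = ', style=bold' if m else ""
            fh.write(f'  "{u}" -- "{v}" [label={w}{style}];\n')
        fh.write("}\n")
    finally:
        if close:
            fh.close()


def export_graphml(instance: InstanceFile, path: PathLike) -> None:
    """Write GraphML with integer ``weight`` and boolean ``matching`` attrs."""
    g = nx.Graph()
    g.add_nodes_from(instance.graph.vertices)
    for u, v, w, m in instance.graph.edges():
        g.add_edge(u, v, weight=w, matching=m)
    if instance.params is not None:
        g.graph["sigma_p"] = instance.params.sigma_p
        g.graph["sigma_c"] = instance.params.sigma_c
        g.graph["k"] = instance.params.k if instance.params.k is not None else 0
    if instance.rsca_params is not None:
        g.graph["ell_p"], g.graph["ell_c"] = instance.rsca_params
    nx.write_graphml(g, str(path))


def import_graphml(path: PathLike) -> InstanceFile:
    g = nx.read_graphml(str(path))
    sg = ScaffoldGraph()
    for v in g.nodes:
        sg.add_vertex(str(v))
    for u, v, data in g.edges(data=True):
        sg.add_edge(str(u), str(v), weight=int(data["weight"]), matching=bool(data["matching"]))
    violations = validate_scaffold_graph(sg)
    if violations:
        raise SGFParseError("invalid scaffold graph: " + "; ".join(violations))
    params = None
    if "sigma_p" in g.graph:
        params = SolveParams(int(g.graph["sigma_p"]), int(g.graph["sigma_c"]), int(g.graph["k"]))
    rsca = None
    if "ell_p" in g.graph:
        rsca = (int(g.graph["ell_p"]), int(g.graph["ell_c"]))
    return InstanceFile(sg, params, rsca)
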