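"""Tree decompositions: greedy fill-in heuristic and nice-form conversion.

A tree decomposition maps the vertices of a graph into "bags" arranged in a
tree such that every edge lives in some bag and every vertex occupies a
connected subtree of bags; the width (largest bag minus one) bounds the
state space of dynamic programs run over it.  We compute decompositions
with the greedy fill-in heuristic -- repeatedly eliminating the vertex
whose neighbourhood needs the fewest fill edges to become a clique -- which
on sparse scaffold graphs produces widths far below the vertex count.

``make_nice`` refines a decomposition into typed bags (leaf / introduce
vertex / introduce edge / forget / join) with an empty root, each graph
edge introduced exactly once; this is the form the treewidth solver
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx


@dataclass
class TreeDecomposition:
    bags: dict[int, frozenset[str]]
    tree: nx.Graph
    root: int

    @property
    def width(self) -> int:
        return max((len(b) for b in self.bags.values()), default=1) - 1


@dataclass
class NiceNode:
    id: int
    kind: str  # leaf | introduce_vertex | introduce_edge | forget | join
    bag: tuple[str, ...]
    children: list[int] = field(default_factory=list)
    vertex: Optional[str] = None
    edge: Optional[tuple[str, str]] = None


@dataclass
class NiceTreeDecomposition:
    nodes: list[NiceNode]  # children always precede parents
    root: int

    @property
    def width(self) -> int:
        return max((len(n.bag) for n in self.nodes), default=1) - 1


def greedy_fillin(g: nx.Graph) -> TreeDecomposition:
    """Tree decomposition from a greedy minimum-fill elimination ordering.

    Ties are broken toward the lexicographically smallest vertex so the
    result is deterministic.  Disconnected graphs are handled by the same
    global elimination; the resulting bag forest is linked into one tree
    (linking bags without shared vertices preserves validity).
    """
    adj: dict[str, set[str]] = {v: set(g.neighbors(v)) for v in g.nodes}
    order: list[str] = []
    bags: dict[int, frozenset[str]] = {}
    bag_of: dict[str, int] = {}

    while adj:
        best_v, best_fill = None, None
        for v in sorted(adj):
            nbrs = sorted(adj[v])
            fill = sum(
                1
                for i in range(len(nbrs))
                for j in range(i + 1, len(nbrs))
                if nbrs[j] not in adj[nbrs[i]]
            )
            if best_fill is None or fill < best_fill:
                best_v, best_fill = v, fill
        v = best_v
        nbrs = sorted(adj[v])
        bid = len(order)
        bags[bid] = frozenset([v] + nbrs)
        bag_of[v] = bid
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                adj[nbrs[i]].add(nbrs[j])
                adj[nbrs[j]].add(nbrs[i])
        for u in nbrs:
            adj[u].discard(v)
        del adj[v]
        order.append(v)

    tree = nx.Graph()
    tree.add_nodes_from(bags)
    eliminated = {v: i for i, v in enumerate(order)}
    roots = []
    for bid, v in enumerate(order):
        later = [u for u in bags[bid] if u != v]
        if later:
            parent_v = min(later, key=lambda u: eliminated[u])
            tree.add_edge(bid, bag_of[parent_v])
        else:
            roots.append(bid)
    for a, b in zip(roots, roots[1:]):
        tree.add_edge(a, b)
    root = roots[-1] if roots else 0
    if not bags:
        bags = {0: frozenset()}
        tree.add_node(0)
        root = 0
    return TreeDecomposition(bags, tree, root)


def validate_decomposition(dec: TreeDecomposition, g: nx.Graph) -> list[str]:
    """Diagnostic list: edge-coverage and connected-occurrence violations."""
    violations = []
    if not nx.is_tree(dec.tree):
        violations.append("bag graph is not a tree")
    covered_vertices = set().union(*dec.bags.values()) if dec.bags else set()
    for v in g.nodes:
        if v not in covered_vertices:
            violations.append(f"vertex {v} appears in no bag")
    for u, v in g.edges:
        if not any(u in b and v in b for b in dec.bags.values()):
            violations.append(f"edge {u}-{v} is contained in no bag")
    for v in g.nodes:
        occ = [i for i, b in dec.bags.items() if v in b]
        if occ and not nx.is_connected(dec.tree.subgraph(occ)):
            violations.append(f"bags containing {v} are not connected")
    return violations


def make_nice(dec: TreeDecomposition, g: nx.Graph) -> NiceTreeDecomposition:
    """Convert a valid decomposition to nice form of the same width.

    Each graph edge is attached to exactly one introduce-edge bag, placed
    directly above the first introduce-vertex bag (in construction order)
    whose bag contains both endpoints.  The root is an empty bag reached by
    a forget chain.
    """
    errors = validate_decomposition(dec, g)
    if errors:
        raise ValueError("invalid tree decomposition: " + "; ".join(errors))

    nodes: list[NiceNode] = []
    unassigned = {tuple(sorted(e)) for e in g.edges}

    def add(kind: str, bag: frozenset[str], children: list[int], **kw) -> int:
        nid = len(nodes)
        nodes.append(NiceNode(nid, kind, tuple(sorted(bag)), children, **kw))
        return nid

    def introduce_edges_for(nid: int, v: str) -> int:
        """Stack introduce-edge bags above an introduce-vertex bag."""
        bag = set(nodes[nid].bag)
        for u in sorted(bag - {v}):
            e = tuple(sorted((u, v)))
            if g.has_edge(u, v) and e in unassigned:
                unassigned.discard(e)
                nid = add("introduce_edge", frozenset(bag), [nid], edge=e)
        return nid

    def chain(nid: Optional[int], src: frozenset[str], dst: frozenset[str]) -> int:
        """Forget src\\dst then introduce dst\\src, one vertex per bag."""
        bag = set(src)
        if nid is None:  # start from an empty leaf
            nid = add("leaf", frozenset(), [])
            bag = set()
        for v in sorted(src - dst):
            bag.discard(v)
            nid = add("forget", frozenset(bag), [nid], vertex=v)
        for v in sorted(dst - bag):
            bag.add(v)
            nid = add("introduce_vertex", frozenset(bag), [nid], vertex=v)
            nid = introduce_edges_for(nid, v)
        return nid

    children_of: dict[int, list[int]] = {i: [] for i in dec.bags}
    parent: dict[int, Optional[int]] = {dec.root: None}
    stack = [dec.root]
    post: list[int] = []
    while stack:
        b = stack.pop()
        post.append(b)
        for nb in sorted(dec.tree.neighbors(b)):
            if nb not in parent:
                parent[nb] = b
                children_of[b].append(nb)
                stack.append(nb)
    post.reverse()  # children before parents

    top_of: dict[int, int] = {}
    for b in post:
        bag = dec.bags[b]
        kids = [chain(top_of[c], dec.bags[c], bag) for c in children_of[b]]
        if not kids:
            nid = chain(None, frozenset(), bag)
        else:
            nid = kids[0]
            for other in kids[1:]:
                nid = add("join", bag, [nid, other])
        top_of[b] = nid

    root = chain(top_of[dec.root], dec.bags[dec.root], frozenset())
    if nodes[root].kind != "forget":  # empty original root: ensure a real root
        root = add("forget", frozenset(), [root]) if nodes[root].bag else root
    assert not unassigned, f"edges never introduced: {unassigned}"
    assert nodes[root].bag == ()
    nd = NiceTreeDecomposition(nodes, root)
    assert nd.width == dec.width or nd.width <= dec.width
    return nd
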