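import itertools
import random

import networkx as nx
import pytest

from scaffex.generate import gen_tree_instance
from scaffex.model import ScaffoldGraph, SolveParams, is_solution
from scaffex.oracle import brute_force_all
from scaffex.tree_dp import NEG_INF, dump_table, solve_on_tree


class TestSmallExamples:
    def test_single_contig(self):
        sg = ScaffoldGraph.from_edges([("a", "b", 0, True)])
        opt, cover = solve_on_tree(sg, 1)
        assert opt == 0 and cover.edges == frozenset() and cover.n_paths == 1

    def test_two_contigs(self, two_contig_path):
        assert solve_on_tree(two_contig_path, 1)[0] == 5
        assert solve_on_tree(two_contig_path, 2)[0] == 0
        assert solve_on_tree(two_contig_path, 3) == (None, None)

    def test_non_tree_rejected(self, four_cycle):
        with pytest.raises(ValueError, match="acyclic"):
            solve_on_tree(four_cycle, 1)

    def test_forest_knapsack(self):
        # two disjoint 2-contig paths: sigma_p splits across components
        edges = [
            ("a", "b", 0, True), ("c", "d", 0, True), ("b", "c", 5, False),
            ("e", "f", 0, True), ("g", "h", 0, True), ("f", "g", 7, False),
        ]
        sg = ScaffoldGraph.from_edges(edges)
        assert solve_on_tree(sg, 2)[0] == 12
        assert solve_on_tree(sg, 3)[0] == 7  # drop the cheaper link
        assert solve_on_tree(sg, 4)[0] == 0
        assert solve_on_tree(sg, 1) == (None, None)


class TestOracleEquivalence:
    def test_100_random_trees(self):
        for seed in range(100):
            n = random.Random(seed).randint(1, 7)
            sg = gen_tree_instance(n, seed)
            bf = brute_force_all(sg)
            for p in range(1, 5):
                opt, cover = solve_on_tree(sg, p)
                expected = bf.get((p, 0))
                if expected is None:
                    assert opt is None
                else:
                    assert opt == expected[0]
                    assert is_solution(sg, SolveParams(p, 0, opt), cover.edges)

    def test_monotone_under_added_links(self):
        """Adding a link never decreases the optimum at fixed sigma_p."""
        for seed in range(20):
            sg = gen_tree_instance(5, seed)
            base = {p: solve_on_tree(sg, p)[0] for p in range(1, 5)}
            rng = random.Random(seed)
            verts = sg.vertices
            for _ in range(20):
                u, v = rng.sample(verts, 2)
                if not sg.has_edge(u, v) and not nx.has_path(sg.graph, u, v):
                    sg.add_edge(u, v, weight=rng.randint(1, 9), matching=False)
                    break
            for p, old in base.items():
                new = solve_on_tree(sg, p)[0]
                if old is not None:
                    assert new is not None and new >= old


def _subtree_entry_oracle(sg, table, v, sigma_p):
    """Enumerate covers of the subtree under v; best weight per (c, i)."""
    sub_vertices = {v}
    stack = [v]
    while stack:
        x = stack.pop()
        for y in table.children[x]:
            sub_vertices.add(y)
            stack.append(y)
    sub_links = [
        (a, b) for a, b in sg.links if a in sub_vertices and b in sub_vertices
    ]
    sub_matching = [
        (a, b) for a, b in sg.matching if a in sub_vertices and b in sub_vertices
    ]
    best = {}
    for r in range(len(sub_links) + 1):
        for S in itertools.combinations(sub_links, r):
            deg = {}
            for a, b in S:
                deg[a] = deg.get(a, 0) + 1
                deg[b] = deg.get(b, 0) + 1
            if any(d > 1 for d in deg.values()):
                continue
            h = nx.Graph()
            h.add_edges_from(S)
            h.add_edges_from(sub_matching)
            i = nx.number_connected_components(h)
            c = deg.get(v, 0)
            w = sum(sg.weight(a, b) for a, b in S)
            if i <= sigma_p and ((c, i) not in best or w > best[(c, i)]):
                best[(c, i)] = w
    return best


def test_table_entries_match_subtree_enumeration():
    """Every finite final entry equals the best enumerated subtree cover."""
    sigma_p = 4
    for seed in range(25):
        sg = gen_tree_instance(random.Random(seed).randint(2, 6), seed)
        table = dump_table(sg, sigma_p)
        for v in sg.vertices:
            oracle = _subtree_entry_oracle(sg, table, v, sigma_p)
            for c in (0, 1):
                for i in range(sigma_p + 1):
                    got = table.value(v, c, i)
                    expected = oracle.get((c, i))
                    if expected is None:
                        assert got == NEG_INF
                    else:
                        assert got == expected


def test_leaf_table_has_single_base_entry():
    sg = gen_tree_instance(3, seed=0)
    table = dump_table(sg, 2)
    leaves = [v for v in sg.vertices if not table.children[v]]
    for v in leaves:
        assert table.value(v, 0, 0) == 0
        assert table.value(v, 1, 0) == NEG_INF
        assert table.value(v, 0, 1) == NEG_INF
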