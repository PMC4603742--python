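import random

import pytest

from scaffex.generate import gen_bounded_tw_instance, gen_rsca_instance
from scaffex.kernel import (
    ReductionNo,
    ReductionTrace,
    RSCAInstance,
    check_kernel_bound,
    check_reduced_structure,
    path_rule_1,
    reduce_instance,
    tree_rule_1,
)
from scaffex.model import ScaffoldGraph, validate_scaffold_graph
from scaffex.oracle import brute_force_rsca
from scaffex.stats import cycle_core


def alt_path(names, link_weight=5) -> list:
    """Edge list of an alternating path over ``names`` starting with a contig."""
    edges = []
    for i in range(len(names) - 1):
        m = i % 2 == 0
        edges.append((names[i], names[i + 1], 0 if m else link_weight, m))
    return edges


def alt_cycle(names, link_weight=5) -> list:
    edges = []
    for i in range(len(names)):
        m = i % 2 == 0
        u, v = names[i], names[(i + 1) % len(names)]
        edges.append((u, v, 0 if m else link_weight, m))
    return edges


def assert_decision_preserved(inst: RSCAInstance):
    before = brute_force_rsca(inst)[0]
    reduced, trace = reduce_instance(inst)
    after = False if reduced is None else brute_force_rsca(reduced)[0]
    assert before == after, (before, after, trace)
    return reduced, trace


class TestTreeRule1:
    def test_exact_length_component_removed(self):
        sg = ScaffoldGraph.from_edges(alt_path(["a", "b", "c", "d"], 7))
        inst = RSCAInstance(sg, 1, 0, 3, 4, k=7)
        trace = ReductionTrace()
        assert tree_rule_1(inst, trace)
        assert inst.graph.n_vertices == 0
        assert inst.sigma_p == 0 and inst.k == 0
        assert trace.records[0].d_k == -7

    def test_short_isolated_path_is_no(self):
        sg = ScaffoldGraph.from_edges(alt_path(["a", "b", "c", "d"]))
        inst = RSCAInstance(sg, 1, 0, 5, 4)
        with pytest.raises(ReductionNo, match="isolated path"):
            tree_rule_1(inst, ReductionTrace())

    def test_splits_long_chained_path(self):
        # two length-3 blocks joined by a link: 7 edges total
        names = [f"x{i}" for i in range(8)]
        sg = ScaffoldGraph.from_edges(alt_path(names))
        inst = RSCAInstance(sg, 2, 0, 3, 4, k=10)  # the two in-block links
        reduced, trace = reduce_instance(inst)
        assert reduced is not None
        assert reduced.graph.n_vertices == 0 and reduced.sigma_p == 0
        assert [r.rule for r in trace.records] == ["tree_rule_1", "tree_rule_1"]
        assert reduced.k <= 0


class TestTreeRule2:
    def test_block_pendant_is_peeled_off_a_cycle(self):
        edges = alt_cycle(["a", "b", "c", "d"])
        edges.append(("a", "p0", 3, False))  # connector link
        edges += alt_path(["p0", "p1", "p2", "p3"])
        sg = ScaffoldGraph.from_edges(edges)
        inst = RSCAInstance(sg, 1, 1, 3, 4, k=10)  # block link 5 + cycle links 2*5 > 10
        reduced, trace = assert_decision_preserved(inst)
        assert reduced is not None
        rules = [r.rule for r in trace.records]
        assert "tree_rule_2" in rules and "tree_rule_1" in rules
        assert reduced.graph.n_vertices == 4  # only the clean cycle remains
        assert reduced.sigma_p == 0

    def test_two_short_branches_force_no(self):
        # two 2-vertex branches at one hull vertex: only one can escape
        edges = alt_cycle(["a", "b", "c", "d"])
        edges += [("a", "p0", 1, False), ("p0", "p1", 0, True)]
        edges += [("a", "r0", 1, False), ("r0", "r1", 0, True)]
        sg = ScaffoldGraph.from_edges(edges)
        inst = RSCAInstance(sg, 2, 0, 3, 4)
        assert not brute_force_rsca(inst)[0]
        reduced, trace = reduce_instance(inst)
        assert reduced is None and trace.status == "no"


class TestTreeRule3:
    def test_link_attached_short_pendant_isolates_its_link(self):
        edges = alt_cycle([f"v{i}" for i in range(8)])
        edges += [("v0", "p0", 2, False), ("p0", "p1", 0, True)]
        sg = ScaffoldGraph.from_edges(edges)
        inst = RSCAInstance(sg, 1, 1, 3, 6)
        work = inst.copy()
        trace = ReductionTrace()
        from scaffex.kernel import tree_rule_3

        applied = tree_rule_3(work, trace, cycle_core(work.graph.graph))
        assert applied
        # v0 keeps only its contig edge and the pendant link
        assert work.graph.degree("v0") == 2
        assert_decision_preserved(inst)


class TestPathRule1:
    def test_long_cycle_contracts_one_period(self):
        names = [f"v{i}" for i in range(12)]
        sg = ScaffoldGraph.from_edges(alt_cycle(names))
        inst = RSCAInstance(sg, 3, 0, 3, 4, k=15)  # keep 3 of the 6 links
        assert brute_force_rsca(inst)[0]
        reduced, trace = assert_decision_preserved(inst)
        assert reduced is not None
        assert "path_rule_1" in [r.rule for r in trace.records]
        assert reduced.graph.n_vertices == 8
        assert reduced.sigma_p == 2

    def test_not_applicable_at_threshold(self):
        # cycle of 8: longest degree-2 path has 7 edges = threshold - 1
        sg = ScaffoldGraph.from_edges(alt_cycle([f"v{i}" for i in range(8)]))
        inst = RSCAInstance(sg, 2, 0, 3, 4)
        assert not path_rule_1(inst, ReductionTrace())


def bent_cycle_instance(pattern):
    """Length-3 blocks on a cycle; blocks flagged in ``pattern`` are bent at s=1.

    A bent block lays only its suffix along the cycle and leaves its first
    contig dangling as a one-edge pendant whose root is a chain vertex.
    """
    edges = []
    entries = []
    for j, bent in enumerate(pattern):
        blk = [f"{chr(ord('p') + j)}{i}" for i in range(4)]
        edges += alt_path(blk, link_weight=4 + j)
        entries.append((blk[1], blk[3]) if bent else (blk[0], blk[3]))
    for j, (_, exit_v) in enumerate(entries):
        edges.append((exit_v, entries[(j + 1) % len(pattern)][0], 2, False))
    sg = ScaffoldGraph.from_edges(edges)
    return RSCAInstance(sg, len(pattern), 0, 3, 4, k=sum(4 + j for j in range(len(pattern))))


class TestPathRule2:
    def test_pendant_between_two_period_chains(self):
        # the chains on both sides of each pendant root have 7 edges: long
        # enough for both period-length arms, short enough to silence the
        # chain-contraction rule
        inst = bent_cycle_instance((0, 1, 0, 1))
        assert brute_force_rsca(inst)[0]
        reduced, trace = assert_decision_preserved(inst)
        rules = [r.rule for r in trace.records]
        assert "path_rule_2" in rules
        assert reduced is not None and reduced.sigma_p < 3

    def test_index_realignment_is_modular(self):
        # gamma = 1, ell_p = 3: i -> (i - 1) mod 4 maps (0,1,2,3) to (3,0,1,2)
        assert [(i - 1) % 4 for i in range(4)] == [3, 0, 1, 2]


class TestPathRule3:
    def test_two_pendant_roots_on_one_cycle(self):
        inst = bent_cycle_instance((1, 1, 0))
        assert brute_force_rsca(inst)[0]
        reduced, trace = assert_decision_preserved(inst)
        assert any(r.rule == "path_rule_3" for r in trace.records)


class TestReduce:
    def test_already_reduced_instance_is_identity(self):
        sg = ScaffoldGraph.from_edges(alt_cycle(["a", "b", "c", "d"]))
        inst = RSCAInstance(sg, 0, 1, 3, 4, k=10)
        reduced, trace = reduce_instance(inst)
        assert trace.records == []
        assert reduced.graph == inst.graph

    def test_count_identity_shortcut(self):
        sg = ScaffoldGraph.from_edges(alt_cycle(["a", "b", "c", "d"]))
        reduced, trace = reduce_instance(RSCAInstance(sg, 1, 1, 3, 4))
        assert reduced is None and "vertex count" in trace.no_reason

    def test_trace_offsets_replay(self):
        for seed in range(20):
            inst = gen_rsca_instance(5, 1, 3, 4, n_pendants=2, n_subdivisions=2, seed=seed)
            reduced, trace = reduce_instance(inst)
            assert reduced is not None
            assert inst.sigma_p + trace.total_d_sigma_p == reduced.sigma_p
            assert inst.k + trace.total_d_k == reduced.k

    def test_reduced_graphs_stay_valid(self):
        for seed in range(20):
            inst = gen_rsca_instance(4, 1, 5, 6, n_pendants=1, n_subdivisions=3, seed=seed)
            reduced, _ = reduce_instance(inst)
            assert reduced is not None
            assert validate_scaffold_graph(reduced.graph) == []

    def test_kernel_bound_on_generated_suite(self):
        for seed in range(40):
            lp = [3, 5][seed % 2]
            lc = [4, 6][(seed // 2) % 2]
            inst = gen_rsca_instance(6, 1, lp, lc, n_pendants=2, n_subdivisions=3, seed=seed)
            reduced, trace = reduce_instance(inst)
            assert trace.status == "reduced"
            assert check_reduced_structure(reduced) == []
            bound = check_kernel_bound(reduced)
            assert bound.ok, bound

    def test_decision_preserved_on_random_instances(self):
        checked = 0
        seed = 0
        while checked < 120:
            seed += 1
            rng = random.Random(seed)
            if rng.random() < 0.5:
                sg = gen_bounded_tw_instance(rng.randint(2, 8), rng.randint(0, 3), seed)
                for u, v in sg.matching:
                    sg.set_weight(u, v, 0)
                inst = RSCAInstance(
                    sg, rng.randint(0, 4), rng.randint(0, 1),
                    rng.choice([1, 3, 5]), rng.choice([4, 6]), rng.randint(0, 30),
                )
            else:
                inst = gen_rsca_instance(
                    rng.randint(1, 3), rng.randint(0, 1),
                    rng.choice([3, 5]), rng.choice([4, 6]),
                    n_pendants=rng.randint(0, 1), n_subdivisions=rng.randint(0, 2),
                    seed=seed,
                )
                if rng.random() < 0.4:
                    inst.k += rng.randint(1, 50)
            if len(inst.graph.links) > 20 or inst.graph.n_vertices > 24:
                continue
            assert_decision_preserved(inst)
            checked += 1
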