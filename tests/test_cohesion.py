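"""Cohesive-subgraph mining: signatures, prunings, and oracle agreement."""

from itertools import product

import pytest

from cismine.cohesion import (
    CohesiveSubgraph,
    MiningConfig,
    is_cohesive,
    is_maximal,
    level_one_keep,
    mine_maximal_cohesive,
    order_candidates,
    prune_covered_siblings,
    same_as_parent_cutoff,
    signature,
)
from cismine.graph import AttributedGraph, CismineError, Graph
from cismine.oracle import brute_force_maximal_cohesive, is_connected_union_find
from cismine.reverse_search import EnumState
from cismine.synth import PlantedModel, planted_attributed_graph

ALL_FLAG_COMBOS = list(product([True, False], repeat=3))


def make_attributed(edges, features, d):
    """features: label -> iterable of set dimension indices."""
    g = Graph.from_edges(edges, extra_vertices=list(features))
    rows = [
        [1 if j in features[lab] else 0 for j in range(d)] for lab in g.labels
    ]
    return AttributedGraph.from_matrix(g, rows)


def member_sets(results):
    return frozenset(r.members for r in results)


class TestSignature:
    def test_empty_set_has_all_dimensions(self):
        ag = make_attributed([("a", "b")], {"a": {0}, "b": {1}}, 4)
        assert signature(ag, []) == 0b1111

    def test_singleton_is_identity(self):
        ag = make_attributed([("a", "b")], {"a": {0, 2}, "b": {1}}, 3)
        assert signature(ag, [ag.graph.id_of("a")]) == 0b101

    def test_pair_is_bitwise_and(self):
        ag = make_attributed(
            [("a", "b")], {"a": {0, 1, 3}, "b": {0, 2, 3}}, 4
        )
        assert signature(ag, [0, 1]) == 0b1001

    def test_cohesion_threshold(self):
        cfg2 = MiningConfig(s_min=2)
        assert is_cohesive(0b1001, cfg2)
        assert not is_cohesive(0b1000, cfg2)
        assert is_cohesive(0, MiningConfig(s_min=0))


class TestCandidateOrderAndPruning:
    def test_order_is_distance_then_id(self):
        g = Graph.from_edges([("a", "b"), ("b", "c"), ("b", "d")])
        state = EnumState(g)
        state.begin_root(0)
        state.extend(1)
        # c and d both at distance 2; b handled already
        assert order_candidates(state, [3, 2]) == [2, 3]
        assert state.D[2] == state.D[3] == 2

    def test_incomparable_signatures_are_both_kept(self):
        ag = make_attributed(
            [("p", "x"), ("p", "y")],
            {"p": {0, 1}, "x": {0}, "y": {1}},
            2,
        )
        parent_sig = 0b11
        keep = prune_covered_siblings(
            ag, parent_sig, [ag.graph.id_of("x"), ag.graph.id_of("y")]
        )
        assert keep == [True, True]

    def test_contained_signature_is_dropped(self):
        ag = make_attributed(
            [("p", "x"), ("p", "y")],
            {"p": {0, 1}, "x": {0, 1}, "y": {0}},
            2,
        )
        keep = prune_covered_siblings(
            ag, 0b11, [ag.graph.id_of("x"), ag.graph.id_of("y")]
        )
        assert keep == [True, False]

    def test_equal_signatures_keep_only_the_earlier(self):
        ag = make_attributed(
            [("p", "x"), ("p", "y")],
            {"p": {0, 1}, "x": {0, 1}, "y": {0, 1}},
            2,
        )
        keep = prune_covered_siblings(
            ag, 0b11, [ag.graph.id_of("x"), ag.graph.id_of("y")]
        )
        assert keep == [True, False]

    def test_level_one_keeps_vertex_without_neighbors(self):
        ag = make_attributed([("a", "b")], {"a": {0}, "b": {0}, "z": {0}}, 1)
        assert level_one_keep(ag, ag.graph.id_of("z"))

    def test_level_one_prunes_covered_larger_vertex(self, attributed_graph):
        g = attributed_graph.graph
        assert not level_one_keep(attributed_graph, g.id_of("C"))
        assert not level_one_keep(attributed_graph, g.id_of("H"))
        assert level_one_keep(attributed_graph, g.id_of("A"))
        assert level_one_keep(attributed_graph, g.id_of("B"))

    def test_same_as_parent_cutoff_is_signature_equality(self):
        assert same_as_parent_cutoff(0b110, 0b110)
        assert not same_as_parent_cutoff(0b110, 0b100)


class TestMaximality:
    def test_isolated_cohesive_vertex_is_maximal(self):
        ag = make_attributed([("a", "b")], {"a": {0}, "b": {0}, "z": {0}}, 1)
        z = ag.graph.id_of("z")
        assert is_maximal(ag, [z], ag.features[z], MiningConfig(s_min=1))

    def test_extension_keeping_enough_dimensions_blocks_maximality(self):
        ag = make_attributed([("a", "b")], {"a": {0, 1}, "b": {0, 1}}, 2)
        a = ag.graph.id_of("a")
        assert not is_maximal(ag, [a], ag.features[a], MiningConfig(s_min=2))

    def test_miner_maximality_matches_definition_on_random_instances(self):
        cfg_flags = MiningConfig
        for seed in range(10):
            inst = planted_attributed_graph(
                PlantedModel(
                    n=10, density=0.3, d=4, modules=((3, 2),),
                    background_rate=0.3, seed=seed,
                )
            )
            ag = inst.agraph
            for s_min in (1, 2):
                results = mine_maximal_cohesive(ag, MiningConfig(s_min=s_min))
                for r in results:
                    assert is_connected_union_find(ag.graph, r.members)
                    assert r.signature == signature(ag, r.members)
                    assert r.signature.bit_count() >= s_min
                    assert is_maximal(ag, r.members, r.signature, MiningConfig(s_min=s_min))


class TestMiner:
    def test_demo_graph_reports_exactly_two_maximal_subgraphs(self, attributed_graph):
        ag = attributed_graph
        g = ag.graph
        results = mine_maximal_cohesive(ag, MiningConfig(s_min=2))
        found = {
            frozenset(g.labels[v] for v in r.members): sorted(ag.dims_of(r.signature))
            for r in results
        }
        assert found == {
            frozenset("ABCFH"): ["d0", "d1"],
            frozenset("ABCGH"): ["d0", "d3"],
        }

    def test_demo_graph_traversal_events(self, attributed_graph):
        """All three prunings fire where the construction says they must."""
        ag = attributed_graph
        g = ag.graph

        def lab(v):
            return g.labels[v] if v >= 0 else None

        events = []
        mine_maximal_cohesive(ag, MiningConfig(s_min=2), on_event=events.append)
        level_one = {(lab(e.vertex), lab(e.witness)) for e in events if e.kind == "level_one"}
        assert level_one == {("C", "B"), ("H", "A")}

        covered = {
            (tuple(lab(v) for v in e.node), lab(e.vertex), lab(e.witness))
            for e in events
            if e.kind == "covered_sibling"
        }
        assert (("A",), "F", "B") in covered
        assert (("A", "B"), "C", "H") in covered
        assert (("A", "B"), "G", "H") in covered

        cut_nodes = {
            tuple(lab(v) for v in e.node)
            for e in events
            if e.kind == "parent_identical"
        }
        assert ("A", "B", "F") in cut_nodes

    def test_parent_identical_cutoff_skips_later_siblings(self, attributed_graph):
        """With covering pruning off, the cutoff itself removes the later
        sibling C at node {A,B,F}."""
        ag = attributed_graph
        g = ag.graph
        events = []
        mine_maximal_cohesive(
            ag,
            MiningConfig(s_min=2, prune_covering_sibling=False),
            on_event=events.append,
        )
        cut = [
            e
            for e in events
            if e.kind == "parent_identical"
            and tuple(g.labels[v] for v in e.node) == ("A", "B", "F")
        ]
        assert len(cut) == 1
        assert tuple(g.labels[v] for v in cut[0].skipped) == ("C",)

    def test_all_zero_attributes_yield_nothing(self):
        ag = make_attributed([("a", "b")], {"a": set(), "b": set()}, 2)
        assert mine_maximal_cohesive(ag, MiningConfig(s_min=1)) == []

    def test_smin_zero_reports_the_connected_components(self):
        ag = make_attributed(
            [("a", "b"), ("x", "y"), ("y", "z")],
            {"a": {0}, "b": set(), "x": {1}, "y": set(), "z": {0}},
            2,
        )
        g = ag.graph
        results = mine_maximal_cohesive(ag, MiningConfig(s_min=0))
        got = {frozenset(g.labels[v] for v in r.members) for r in results}
        assert got == {frozenset("ab"), frozenset("xyz")}

    def test_smin_above_dimension_count_is_an_error(self):
        ag = make_attributed([("a", "b")], {"a": {0}, "b": {0}}, 2)
        with pytest.raises(CismineError, match="S_min exceeds"):
            mine_maximal_cohesive(ag, MiningConfig(s_min=3))

    def test_pruning_flags_never_change_the_result(self):
        """Soundness and completeness: every on/off combination of the three
        prunings yields the identical set of maximal subgraphs, equal to the
        brute-force oracle."""
        for seed in range(15):
            inst = planted_attributed_graph(
                PlantedModel(
                    n=11, density=0.3, d=5, modules=((4, 3),),
                    background_rate=0.25, seed=seed,
                )
            )
            ag = inst.agraph
            for s_min in (1, 2, 3):
                oracle = brute_force_maximal_cohesive(ag, s_min).sets
                for flags in ALL_FLAG_COMBOS:
                    got = member_sets(
                        mine_maximal_cohesive(ag, MiningConfig(s_min, *flags))
                    )
                    assert got == oracle, (seed, s_min, flags)

    def test_reported_collection_is_an_antichain(self):
        for seed in range(10):
            inst = planted_attributed_graph(
                PlantedModel(
                    n=12, density=0.35, d=6, modules=((4, 3),),
                    background_rate=0.3, seed=100 + seed,
                )
            )
            results = mine_maximal_cohesive(inst.agraph, MiningConfig(s_min=2))
            sets = [r.members for r in results]
            assert len(sets) == len(set(sets))
            for i, a in enumerate(sets):
                for b in sets[i + 1:]:
                    assert not (a < b or b < a)

    def test_lower_threshold_absorbs_higher_threshold_sets(self):
        """Each maximal set at threshold t is contained in some maximal set
        at any lower threshold t'."""
        inst = planted_attributed_graph(
            PlantedModel(
                n=12, density=0.35, d=6, modules=((4, 4),),
                background_rate=0.35, seed=7,
            )
        )
        ag = inst.agraph
        by_t = {
            t: member_sets(mine_maximal_cohesive(ag, MiningConfig(s_min=t)))
            for t in (1, 2, 3)
        }
        for hi, lo in ((3, 2), (2, 1)):
            for s in by_t[hi]:
                assert any(s <= big for big in by_t[lo])

    def test_planted_modules_are_recovered(self):
        """Two disjoint planted modules on a clean background are reported
        exactly; with background noise each module is contained in some
        reported set."""
        model = PlantedModel(
            n=20, density=0.1, d=8, modules=((5, 4), (5, 4)),
            background_rate=0.0, seed=3,
        )
        inst = planted_attributed_graph(model)
        results = mine_maximal_cohesive(inst.agraph, MiningConfig(s_min=3))
        got = member_sets(results)
        assert got == frozenset(m.vertices for m in inst.modules)

        for seed in range(20):
            noisy = planted_attributed_graph(
                PlantedModel(
                    n=20, density=0.1, d=8, modules=((5, 4), (5, 4)),
                    background_rate=0.1, seed=seed,
                )
            )
            reported = member_sets(
                mine_maximal_cohesive(noisy.agraph, MiningConfig(s_min=3))
            )
            for mod in noisy.modules:
                assert any(mod.vertices <= s for s in reported), seed
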