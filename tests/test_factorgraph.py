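"""Monotone maps, factor graphs, essentiality, copies, and signal paths."""

import pytest

from switchdyn.network import Orientation, RegulatoryEdge, Sign, network_from_edges
from switchdyn.factorgraph import (
    CapacityError,
    FactorGraph,
    count_monotone_maps_bruteforce,
    edge_essentiality,
    enumerate_assignments,
    enumerate_copies,
    enumerate_monotone_maps,
    enumerate_partial_paths,
    essential_vertices,
    factor_is_essential,
    is_essential_assignment,
    low_and_high_nodes,
    parameter_graph_size,
)
from switchdyn.pathcount import SignalDAG, hysteresis_automaton, resettable_automaton
from switchdyn.queries import MorseState, path_has_hysteresis, path_has_resettable_bistability
from switchdyn import fixtures


class TestMonotoneMaps:
    @pytest.mark.parametrize("s", [0, 1, 2, 3])
    @pytest.mark.parametrize("t", [1, 2, 3])
    def test_counts_match_bruteforce(self, s, t):
        maps = enumerate_monotone_maps(s, t)
        assert len(maps) == count_monotone_maps_bruteforce(s, t)
        assert len(set(maps)) == len(maps)

    @pytest.mark.parametrize(
        "s,t,count", [(1, 1, 3), (0, 2, 3), (2, 1, 6)]
    )
    def test_known_counts(self, s, t, count):
        assert len(enumerate_monotone_maps(s, t)) == count

    def test_all_maps_monotone(self):
        for g in enumerate_monotone_maps(3, 2):
            for a in range(8):
                for k in range(3):
                    if not a >> k & 1:
                        assert g[a] <= g[a | 1 << k]

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            enumerate_monotone_maps(5, 3, cap=10**4)


class TestFactorGraph:
    def test_toggle_node_is_three_vertex_path(self, toggle):
        fg = FactorGraph(toggle, "x1")
        assert len(fg) == 3
        assert fg.edges() == [(0, 1), (1, 2)]

    def test_two_input_two_output_node(self):
        net = network_from_edges(
            ["a", "b", "c"],
            [
                RegulatoryEdge("a", "b", Sign.ACTIVATING),
                RegulatoryEdge("a", "c", Sign.ACTIVATING),
                RegulatoryEdge("b", "a", Sign.ACTIVATING),
                RegulatoryEdge("c", "a", Sign.REPRESSING),
            ],
        )
        fg = FactorGraph(net, "a")
        assert (fg.n_inputs, fg.n_outputs) == (2, 2)
        assert len(fg) == count_monotone_maps_bruteforce(2, 2) * 2

    def test_twelve_vertices_for_1_in_2_out(self):
        net = network_from_edges(
            ["a", "b", "c"],
            [
                RegulatoryEdge("b", "a", Sign.ACTIVATING),
                RegulatoryEdge("a", "b", Sign.ACTIVATING),
                RegulatoryEdge("a", "c", Sign.ACTIVATING),
                RegulatoryEdge("c", "b", Sign.ACTIVATING),
            ],
        )
        fg = FactorGraph(net, "a")
        assert (fg.n_inputs, fg.n_outputs) == (1, 2)
        assert len(fg) == 6 * 2

    def test_zero_input_node(self, start):
        fg = FactorGraph(start, "Cln3")
        assert len(fg) == 2
        assert fg.edges() == [(0, 1)]

    def test_every_edge_is_unit_distance(self, start):
        # independent recheck of the adjacency rule on a (2,1) factor
        fg = FactorGraph(start, "Whi5")
        for i, j in fg.edges():
            a, b = fg.vertices[i], fg.vertices[j]
            order_diff = a.order != b.order
            g_diff = sum(abs(x - y) for x, y in zip(a.g, b.g))
            assert (order_diff and g_diff == 0) or (not order_diff and g_diff == 1)

    def test_product_size_on_fixtures(self):
        for net in (
            fixtures.toggle_switch(),
            fixtures.start_network(),
            fixtures.five_node_best(),
            fixtures.e2f_rb_top(),
        ):
            expected = 1
            for n in net.nodes:
                expected *= len(FactorGraph(net, n))
            assert parameter_graph_size(net) == expected

    def test_toggle_parameter_graph_has_nine_vertices(self, toggle):
        assert parameter_graph_size(toggle) == 9


class TestLowHighAndPaths:
    def test_low_high_zero_input(self, start):
        fg = FactorGraph(start, "Cln3")
        lows, highs = low_and_high_nodes(fg)
        assert lows == [0] and highs == [1]

    def test_low_high_one_input(self, toggle):
        fg = FactorGraph(toggle, "x1")
        lows, highs = low_and_high_nodes(fg)
        assert [fg.vertices[i].g for i in lows] == [(0, 0)]
        assert [fg.vertices[i].g for i in highs] == [(1, 1)]

    def test_low_high_two_inputs(self, start):
        fg = FactorGraph(start, "Whi5")
        lows, highs = low_and_high_nodes(fg)
        assert len(fg) == 6 and len(lows) == 1 and len(highs) == 1

    def test_zero_input_single_full_path(self, start):
        fg = FactorGraph(start, "Cln3")
        assert fg.full_paths() == [(0, 1)]

    def test_toggle_unique_full_path(self, toggle):
        fg = FactorGraph(toggle, "x1")
        assert fg.full_paths() == [(0, 1, 2)]

    def test_two_full_paths_through_projections(self, start):
        fg = FactorGraph(start, "Whi5")
        paths = fg.full_paths()
        assert len(paths) == 2
        for p in paths:
            assert len(p) == 5  # T * 2^S steps + 1
            gs = [fg.vertices[v].g for v in p]
            for a, b in zip(gs, gs[1:]):
                assert sum(y - x for x, y in zip(a, b)) == 1

    def test_reversed_orientation_reverses_paths(self, start):
        fg = FactorGraph(start, "Whi5")
        fwd = fg.full_paths(Orientation.DIRECT)
        rev = fg.full_paths(Orientation.REVERSED)
        assert rev == [tuple(reversed(p)) for p in fwd]

    def test_partial_path_triangle_count(self, toggle):
        fg = FactorGraph(toggle, "x1")
        fulls = fg.full_paths()
        assert len(enumerate_partial_paths(fulls)) == 3 * 4 // 2

    def test_partial_paths_two_branches(self, start):
        fg = FactorGraph(start, "Whi5")
        assert len(enumerate_partial_paths(fg.full_paths())) == 24

    def test_partial_paths_empty(self):
        assert enumerate_partial_paths([]) == []

    def test_dag_counts_agree_with_enumeration(self, toggle, start):
        for net, node in ((toggle, "x1"), (start, "Whi5"), (start, "Cln3")):
            fg = FactorGraph(net, node)
            dag = SignalDAG(fg, Orientation.DIRECT)
            assert dag.n_full_paths() == len(fg.full_paths())
            assert dag.n_partial_paths() == len(
                enumerate_partial_paths(fg.full_paths())
            )

    def test_dag_accept_counts_agree_with_per_path_evaluation(self, start):
        """The automaton DP and explicit path classification are two routes
        to the same counts."""
        fg = FactorGraph(start, "Whi5")
        dag = SignalDAG(fg, Orientation.DIRECT)
        labels = [
            MorseState.QS_MONO,
            MorseState.BI_QS_PS,
            MorseState.BI_QS_PS,
            MorseState.OTHER,
            MorseState.PS_MONO,
            MorseState.PS_MONO,
        ]
        fulls = fg.full_paths()
        partials = enumerate_partial_paths(fulls)
        for aut, pred in (
            (hysteresis_automaton(), path_has_hysteresis),
            (resettable_automaton("QS", False),
             lambda s: path_has_resettable_bistability(s, "QS")),
        ):
            for universe, paths in (("full", fulls), ("partial", partials)):
                expected = sum(1 for p in paths if pred([labels[v] for v in p]))
                assert dag.count_accepted(labels, aut, universe) == expected


class TestEssentiality:
    def test_toggle_nonconstant_both_essential(self, toggle):
        fgs = {n: FactorGraph(toggle, n) for n in toggle.nodes}
        mid = {n: fgs[n].vertices[1] for n in toggle.nodes}  # identity maps
        for e in toggle.edges:
            assert edge_essentiality(toggle, mid, e) == (True, True)
        assert is_essential_assignment(toggle, mid)

    def test_constant_factor_never_essential(self, toggle):
        fgs = {n: FactorGraph(toggle, n) for n in toggle.nodes}
        a = {"x1": fgs["x1"].vertices[0], "x2": fgs["x2"].vertices[1]}
        assert not is_essential_assignment(toggle, a)

    def test_zero_input_node_output_inessential(self, start):
        a = {n: FactorGraph(start, n).vertices[-1] for n in start.nodes}
        edge = start.in_edges("Whi5")[0]  # Cln3 -| Whi5
        input_ess, output_ess = edge_essentiality(start, a, edge)
        assert output_ess is False
        assert not is_essential_assignment(start, a)

    def test_two_input_maps(self, start):
        # AND-like map depends on both inputs; a projection ignores one
        whi5 = FactorGraph(start, "Whi5")
        and_map = next(f for f in whi5.vertices if f.g == (0, 0, 0, 1))
        proj = next(f for f in whi5.vertices if f.g == (0, 1, 0, 1))
        assert factor_is_essential(start, "Whi5", and_map)
        assert not factor_is_essential(start, "Whi5", proj)

    def test_start_sbf_has_one_essential_vertex(self, start):
        fg = FactorGraph(start, "SBF")
        ess = essential_vertices(start, fg)
        assert len(ess) == 1
        assert fg.vertices[ess[0]].g == (0, 1)


class TestCopies:
    def test_toggle_three_copies_without_filter(self, toggle):
        copies = enumerate_copies(toggle, "x1", chain=("x1",), essential=False)
        assert len(copies) == 3

    def test_toggle_one_essential_copy(self, toggle):
        copies = enumerate_copies(toggle, "x1", chain=("x1",), essential=True)
        assert len(copies) == 1
        assert dict(copies[0].fixed)["x2"].g == (0, 1)

    def test_product_structure(self, start):
        # chain nodes keep all factors, non-chain nodes essential ones
        copies = enumerate_copies(
            start, "Whi5", chain=("Cln3", "Whi5"), essential=True
        )
        assert len(copies) == 2  # Cln3 free (2) x SBF (1) x Cln2 (1)

    def test_copy_lifts_assignment(self, toggle):
        copies = enumerate_copies(toggle, "x1", chain=("x1",), essential=False)
        fg = FactorGraph(toggle, "x1")
        a = copies[0].assignment_for(fg.vertices[2])
        assert set(a) == {"x1", "x2"}
        assert a["x1"].g == (1, 1)

    def test_assignment_enumeration_covers_product(self, toggle):
        assert len(list(enumerate_assignments(toggle))) == 9
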