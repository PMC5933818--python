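"""Phenotype classification, path predicates, and prevalence statistics."""

import pytest
from hypothesis import given, settings, strategies as st

from switchdyn.network import parse_network
from switchdyn.queries import (
    MorseState,
    PhenotypeConfig,
    classify_phenotype,
    compute_prevalence,
    path_has_hysteresis,
    path_has_resettable_bistability,
)
from switchdyn.dynamics import MorseGraph, MorseNode
from switchdyn.factorgraph import FactorGraph, enumerate_copies, enumerate_partial_paths
from switchdyn import fixtures

QS, PS, B = MorseState.QS_MONO, MorseState.PS_MONO, MorseState.BI_QS_PS
BQ, BP, O = MorseState.BI_QS_STAR, MorseState.BI_PS_STAR, MorseState.OTHER


def mg_from_fps(*fps, extra_cycle=False):
    """A Morse graph consisting only of minimal nodes (enough for classification)."""
    nodes = [MorseNode(frozenset({fp}), fp) for fp in fps]
    if extra_cycle:
        nodes.append(MorseNode(frozenset({(9, 9, 9), (9, 9, 8)}), None))
    return MorseGraph(nodes, set())


class TestClassification:
    @pytest.fixture
    def net3(self):
        return fixtures.e2f_rb_top()

    @pytest.fixture
    def cfg(self):
        return PhenotypeConfig(receiving_node="MD", phenotype_node="EE")

    def test_quiescent_monostable(self, net3, cfg):
        assert classify_phenotype(mg_from_fps((0, 1, 0)), net3, cfg) is QS

    def test_proliferative_monostable_any_positive_level(self, net3, cfg):
        assert classify_phenotype(mg_from_fps((1, 0, 2)), net3, cfg) is PS

    def test_bistable_qs_ps(self, net3, cfg):
        assert classify_phenotype(mg_from_fps((0, 1, 0), (1, 0, 1)), net3, cfg) is B

    def test_extra_attractors_keep_bistable(self, net3, cfg):
        mg = mg_from_fps((0, 1, 0), (1, 0, 1), extra_cycle=True)
        assert classify_phenotype(mg, net3, cfg) is B

    def test_cycle_attractor_is_wildcard(self, net3, cfg):
        mg = mg_from_fps((0, 1, 0), extra_cycle=True)
        assert classify_phenotype(mg, net3, cfg) is BQ or classify_phenotype(mg, net3, cfg) is O
        # a lone QS-FP plus a cycle is not (QS, *) bistability: * must be an FP
        assert classify_phenotype(mg, net3, cfg) is O

    def test_unknown_phenotype_node_is_error(self, net3):
        bad = PhenotypeConfig(receiving_node="MD", phenotype_node="nope")
        with pytest.raises(ValueError):
            classify_phenotype(mg_from_fps((0, 0, 0)), net3, bad)


class TestPathPredicates:
    @pytest.mark.parametrize(
        "states,expected",
        [
            ([QS, B], True),
            ([QS, O, B], False),
            ([QS, BQ, B], True),
            ([QS, B, PS], True),   # prefix semantics
            ([PS, B], False),
            ([QS], False),
        ],
    )
    def test_resettable_to_qs(self, states, expected):
        assert path_has_resettable_bistability(states, "QS") is expected

    def test_whole_path_mode_rejects_trailing_ps(self):
        assert path_has_resettable_bistability([QS, B, PS], "QS", whole_path=True) is False
        assert path_has_resettable_bistability([QS, B, B], "QS", whole_path=True) is True

    @pytest.mark.parametrize(
        "states,expected",
        [
            ([QS, B, PS], True),
            ([QS, PS], False),
            ([QS, B, QS], False),
            ([QS, QS, B, B, PS, PS], True),
            ([QS, B, O, B, PS], True),   # unclassified middle allowed
            ([O, B, PS], False),
        ],
    )
    def test_hysteresis(self, states, expected):
        assert path_has_hysteresis(states) is expected

    def test_strict_hysteresis_rejects_gaps(self):
        assert path_has_hysteresis([QS, B, O, B, PS], strict=True) is False
        assert path_has_hysteresis([QS, B, B, PS], strict=True) is True

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            path_has_resettable_bistability([], "QS")
        with pytest.raises(ValueError):
            path_has_hysteresis([])

    @given(
        st.lists(
            st.sampled_from([QS, PS, B, BQ, BP, O]), min_size=1, max_size=8
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_hysteresis_implies_resettable_both_ways(self, states):
        if path_has_hysteresis(states):
            assert path_has_resettable_bistability(states, "QS")
            assert path_has_resettable_bistability(list(reversed(states)), "PS")


class TestPrevalence:
    def test_toggle_hysteresis_one_copy_in_three(self, toggle):
        cfg = PhenotypeConfig(
            receiving_node="x1", phenotype_node="x1", essential_filter=False
        )
        rep = compute_prevalence(toggle, cfg)
        assert rep.query_node == "x1"
        assert rep.n_copies == 3 and rep.n_full_paths == 1
        qc = rep.counts["hysteresis_full"]
        assert (qc.numerator_pairs, qc.denominator_pairs) == (1, 3)
        assert rep.percentage("hysteresis", "full", "by_copy") == pytest.approx(100 / 3)

    def test_toggle_lifted_g2_sequence(self, toggle):
        """The only hysteretic copy is the one fixing the partner's
        switching factor; its lifted full path reads OFF -> bistable -> ON."""
        cfg = PhenotypeConfig(
            receiving_node="x1", phenotype_node="x1", essential_filter=False
        )
        from switchdyn.queries import _LabelEngine

        fg = FactorGraph(toggle, "x1")
        copies = enumerate_copies(toggle, "x1", chain=("x1",), essential=False)
        eng = _LabelEngine(toggle, cfg, "x1")
        seqs = []
        for c in copies:
            labels = eng.labels_for_copy(dict(c.fixed), fg)
            seqs.append([labels[v] for v in fg.full_paths()[0]])
        assert [QS, B, PS] in seqs
        assert sum(1 for s in seqs if s == [QS, B, PS]) == 1

    def test_top3_full_path_hysteresis_complete(self, top3):
        cfg = PhenotypeConfig(receiving_node="MD", phenotype_node="EE")
        for strict in (False, True):
            rep = compute_prevalence(
                top3,
                PhenotypeConfig(
                    receiving_node="MD", phenotype_node="EE", strict_hysteresis=strict
                ),
            )
            assert rep.percentage("hysteresis", "full", "by_pair") == 100.0
            assert rep.percentage("hysteresis", "full", "by_copy") == 100.0

    def test_denominators_are_products(self, start):
        cfg = PhenotypeConfig(receiving_node="Cln3", phenotype_node="SBF")
        rep = compute_prevalence(start, cfg)
        for key, qc in rep.counts.items():
            paths = rep.n_full_paths if key.endswith("_full") else rep.n_partial_paths
            assert qc.denominator_pairs == rep.n_copies * paths
            assert 0 <= qc.pct_pairs <= 100
            assert qc.numerator_pairs <= qc.denominator_pairs

    def test_zero_copies_warns_not_raises(self):
        # RP has no inputs here, so its out-edge can never be essential
        net = parse_network("MD : (EE)\nRP :\nEE : (~RP)(MD)")
        cfg = PhenotypeConfig(receiving_node="MD", phenotype_node="EE")
        rep = compute_prevalence(net, cfg)
        assert rep.n_copies == 0
        assert rep.warning is not None
        assert rep.counts["hysteresis_full"].pct_pairs == 0.0

    def test_pass_through_invariance(self, start):
        """Inserting a single-input single-output activating relay on the
        signal chain (growth module split) leaves every prevalence
        percentage unchanged."""
        five = fixtures.five_node_best()
        cfg_a = PhenotypeConfig(receiving_node="Cln3", phenotype_node="SBF")
        cfg_b = PhenotypeConfig(receiving_node="Myc", phenotype_node="E2F")
        rep_a = compute_prevalence(start, cfg_a)
        rep_b = compute_prevalence(five, cfg_b)
        for q in ("resettable_qs", "resettable_ps", "hysteresis"):
            for u in ("full", "partial"):
                for norm in ("by_pair", "by_copy"):
                    assert rep_a.percentage(q, u, norm) == pytest.approx(
                        rep_b.percentage(q, u, norm)
                    ), (q, u, norm)

    def test_chain_sign_flip_reverses_path_orientation(self, start):
        """Flipping the sign of the head chain edge is equivalent to
        reversing every reported path: the multiset of lifted label
        sequences of the flipped network equals the reversed sequences of
        the original (the head node's two constant factors swap roles)."""
        from switchdyn.queries import _LabelEngine
        from switchdyn.network import contract_input_chain

        flipped = parse_network(fixtures.START_TEXT.replace("(~Cln3)", "(Cln3)"))
        cfg = PhenotypeConfig(receiving_node="Cln3", phenotype_node="SBF")

        def sequences(net, orientation_override=None):
            red = contract_input_chain(net, "Cln3")
            fg = FactorGraph(net, red.query_node)
            orient = orientation_override or red.orientation
            fulls = fg.full_paths(orient)
            eng = _LabelEngine(net, cfg, red.query_node)
            out = []
            for c in enumerate_copies(net, red.query_node, chain=red.chain):
                labels = eng.labels_for_copy(dict(c.fixed), fg)
                out.extend(tuple(labels[v] for v in p) for p in fulls)
            return sorted(out), red.orientation

        seqs_orig, orient_orig = sequences(start)
        seqs_flip, orient_flip = sequences(flipped)
        assert orient_orig.value == "reversed" and orient_flip.value == "direct"
        assert sorted(tuple(reversed(s)) for s in seqs_orig) == seqs_flip

    def test_hysteretic_full_path_contains_resettable_partial(self, start):
        """Every full path flagged hysteretic has a resettable-to-QS prefix
        among the partial paths (explicit-path cross-check)."""
        from switchdyn.queries import _LabelEngine
        from switchdyn.network import contract_input_chain

        cfg = PhenotypeConfig(receiving_node="Cln3", phenotype_node="SBF")
        red = contract_input_chain(start, "Cln3")
        fg = FactorGraph(start, red.query_node)
        fulls = fg.full_paths(red.orientation)
        partials = enumerate_partial_paths(fulls)
        copies = enumerate_copies(start, red.query_node, chain=red.chain)
        eng = _LabelEngine(start, cfg, red.query_node)
        checked = 0
        for c in copies:
            labels = eng.labels_for_copy(dict(c.fixed), fg)
            for p in fulls:
                if path_has_hysteresis([labels[v] for v in p]):
                    checked += 1
                    assert any(
                        set(q) <= set(p)
                        and path_has_resettable_bistability([labels[v] for v in q], "QS")
                        for q in partials
                    )
        assert checked > 0
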