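"""Phenotype classification and path queries: bistability, resettability, hysteresis.

A Morse graph is summarized by the fixed-point attractors it contains,
read through a phenotype node (for restriction-point networks the free
E2F / SBF species): the quiescent state QS is an FP whose phenotype
coordinate is 0, the proliferative state PS an FP whose phenotype
coordinate is at least 1.  The external signal corresponds to monotone
paths through the query node's factor graph; classifying the Morse graph
at each lifted vertex turns a path into a sequence of phenotype states,
on which resettable bistability and hysteresis are decided.

Two prevalence normalizations are reported side by side, because both
appear in the screening literature: the fraction of lifted (copy, path)
pairs exhibiting a query, and the fraction of copies (subgraphs of the
parameter graph) in which at least one path exhibits it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .network import (
    Orientation,
    RegulatoryNetwork,
    Sign,
    contract_input_chain,
)
from .factorgraph import (
    FactorGraph,
    FactorNode,
    enumerate_copies,
)
from .dynamics import MorseGraph, attractor_summary, enumerate_domains
from .queries_states import MorseState
from .pathcount import (
    Automaton,
    JointSignalDAG,
    SignalDAG,
    hysteresis_automaton,
    resettable_automaton,
    strict_hysteresis_automaton,
)

#: States compatible with remaining "resettable to QS" along a path.
_QS_COMPATIBLE = {MorseState.QS_MONO, MorseState.BI_QS_PS, MorseState.BI_QS_STAR}
_PS_COMPATIBLE = {MorseState.PS_MONO, MorseState.BI_QS_PS, MorseState.BI_PS_STAR}


@dataclass(frozen=True)
class PhenotypeConfig:
    """Where the signal enters and which node reports the phenotype."""

    receiving_node: str
    phenotype_node: str
    essential_filter: bool = True
    #: if True, a path exhibits resettable bistability only when *every*
    #: vertex is compatible with the reset state (the entire path consists
    #: of the monostable state and bistable states); if False, a
    #: compatible prefix reaching a (QS, PS)-bistable vertex suffices.
    whole_path_resettable: bool = False
    #: if True, hysteresis requires the strict segment pattern QS+ B+ PS+.
    strict_hysteresis: bool = False
    #: if True, the signal sweeps the factors of the pass-through chain
    #: nodes jointly with the query node's (monotone interleavings in the
    #: product of their factor chains); if False, chain-node factors are
    #: held fixed within each copy and only PG(W) is swept.
    sweep_chain_factors: bool = False


class ConfigurationError(ValueError):
    pass


def _classify(n_attractors: int, fp_coords: Sequence[int]) -> MorseState:
    """Classification from the attractor count and the phenotype coordinate
    of each fixed-point attractor."""
    has_qs = any(c == 0 for c in fp_coords)
    has_ps = any(c >= 1 for c in fp_coords)
    if n_attractors == 1:
        if has_qs:
            return MorseState.QS_MONO
        if has_ps:
            return MorseState.PS_MONO
        return MorseState.OTHER
    if has_qs and has_ps:
        return MorseState.BI_QS_PS
    if len(fp_coords) >= 2 and has_qs:
        return MorseState.BI_QS_STAR
    if len(fp_coords) >= 2 and has_ps:
        return MorseState.BI_PS_STAR
    return MorseState.OTHER


def classify_phenotype(
    mg: MorseGraph, net: RegulatoryNetwork, cfg: PhenotypeConfig
) -> MorseState:
    """Classify one Morse graph by its minimal (attractor) nodes.

    Non-FP attractors never count as QS or PS; they are wildcards that
    make a single-attractor Morse graph OTHER and otherwise leave the
    classification to the FP attractors present.
    """
    if cfg.phenotype_node not in net.nodes:
        raise ConfigurationError(f"phenotype node {cfg.phenotype_node!r} not in network")
    if net.n_outputs(cfg.phenotype_node) < 1:
        raise ConfigurationError("phenotype node has no threshold to cross")
    p = net.node_index(cfg.phenotype_node)
    attractors = mg.attractors()
    fp_coords = [m.fp_label[p] for m in attractors if m.is_fp]
    return _classify(len(attractors), fp_coords)


def path_has_resettable_bistability(
    states: Sequence[MorseState],
    reset_to: str = "QS",
    whole_path: bool = False,
) -> bool:
    """Decide resettable (QS, PS) bistability to ``reset_to`` on a state sequence.

    ``states`` is ordered from the signal-withdrawn end: withdrawing the
    signal from the bistable vertex must lead back to the monostable
    ``reset_to`` state through vertices that never lose that state.  With
    ``whole_path=False`` (the literal reading) a compatible prefix from the
    monostable state to a (QS, PS)-bistable vertex suffices; with
    ``whole_path=True`` the entire sequence must stay compatible.
    """
    if not states:
        raise ValueError("empty state sequence")
    aut = resettable_automaton(reset_to, whole_path)
    q = aut.init(states[0])
    for s in states[1:]:
        q = aut.step(q, s)
    return q in aut.accepting


def path_has_hysteresis(
    states: Sequence[MorseState], strict: bool = False
) -> bool:
    """Hysteresis between QS and PS on a full signal sweep.

    The sequence, ordered from the signal-low end, must exhibit resettable
    bistability to QS from the low end and resettable bistability to PS
    from the high end: the classic QS ... B ... PS traversal in which the
    direction of the signal decides the state inside the bistable window.
    ``strict`` demands the segment pattern QS+ B+ PS+ instead.
    """
    if not states:
        raise ValueError("empty state sequence")
    aut = strict_hysteresis_automaton() if strict else hysteresis_automaton()
    q = aut.init(states[0])
    for s in states[1:]:
        q = aut.step(q, s)
    return q in aut.accepting


# ---------------------------------------------------------------------------
# Prevalence


@dataclass
class QueryCounts:
    numerator_pairs: int = 0
    denominator_pairs: int = 0
    numerator_copies: int = 0
    denominator_copies: int = 0

    @property
    def pct_pairs(self) -> float:
        return (
            100.0 * self.numerator_pairs / self.denominator_pairs
            if self.denominator_pairs
            else 0.0
        )

    @property
    def pct_copies(self) -> float:
        return (
            100.0 * self.numerator_copies / self.denominator_copies
            if self.denominator_copies
            else 0.0
        )

    def as_dict(self) -> dict:
        return {
            "by_pair": {
                "numerator": self.numerator_pairs,
                "denominator": self.denominator_pairs,
                "percentage": self.pct_pairs,
            },
            "by_copy": {
                "numerator": self.numerator_copies,
                "denominator": self.denominator_copies,
                "percentage": self.pct_copies,
            },
        }


@dataclass
class PrevalenceReport:
    """Counts of signal paths exhibiting each phenotype query.

    For each query (resettable to QS, resettable to PS, hysteresis) and
    each path universe (full, partial) two normalizations are kept: by
    (copy, path) pairs — the fraction of lifted paths exhibiting the
    query — and by copies — the fraction of subgraphs in which some path
    exhibits it.
    """

    network: str
    query_node: str
    chain: tuple[str, ...]
    orientation: str
    n_copies: int
    n_full_paths: int
    n_partial_paths: int
    counts: dict[str, QueryCounts] = field(default_factory=dict)
    warning: str | None = None
    metadata: dict = field(default_factory=dict)

    def percentage(
        self, query: str, paths: str = "full", normalization: str = "by_pair"
    ) -> float:
        qc = self.counts[f"{query}_{paths}"]
        return qc.pct_pairs if normalization == "by_pair" else qc.pct_copies

    def as_dict(self) -> dict:
        return {
            "network": self.network,
            "query_node": self.query_node,
            "chain": list(self.chain),
            "orientation": self.orientation,
            "n_copies": self.n_copies,
            "n_full_paths": self.n_full_paths,
            "n_partial_paths": self.n_partial_paths,
            "counts": {k: v.as_dict() for k, v in self.counts.items()},
            "warning": self.warning,
            "metadata": self.metadata,
        }


_QUERIES = ("resettable_qs", "resettable_ps", "hysteresis")


class _LabelEngine:
    """Computes Morse-state labels for every vertex of PG(W) in one copy.

    Works on index-encoded domains.  Within one threshold order of W the
    flow targets of all other nodes are constant (they depend on W's order
    through threshold ranks, never on W's map), so they are computed once
    per (copy, order) and only W's column is refreshed per map.  Attractor
    summaries are memoized on the full flow-target table, which many
    parameter vertices share.
    """

    def __init__(self, net: RegulatoryNetwork, cfg: PhenotypeConfig, w: str):
        self.net = net
        self.cfg = cfg
        self.w = w
        self.nodes = net.nodes
        self.n = len(net.nodes)
        self.w_idx = net.node_index(w)
        self.p_idx = net.node_index(cfg.phenotype_node)
        self.radix = [net.n_outputs(nd) + 1 for nd in net.nodes]
        self.domains = enumerate_domains(net)
        self.d_index = {d: i for i, d in enumerate(self.domains)}
        self.in_specs = {
            nd: [
                (net.node_index(e.source), e.source, e.sign is Sign.ACTIVATING)
                for e in net.in_edges(nd)
            ]
            for nd in net.nodes
        }
        # neighbor indices per coordinate step
        self.strides = [0] * self.n
        s = 1
        for i in range(self.n - 1, -1, -1):
            self.strides[i] = s
            s *= self.radix[i]
        # interning: flow-target columns to small ids, so that memo keys
        # for whole tables are tuples of ints rather than of long tuples
        self._col_ids: dict[tuple, int] = {}
        self._cols: list[tuple] = []
        self._memo: dict[tuple, MorseState] = {}

    def _intern(self, col: tuple) -> int:
        cid = self._col_ids.get(col)
        if cid is None:
            cid = len(self._cols)
            self._col_ids[col] = cid
            self._cols.append(col)
        return cid

    def _bits(self, assignment: dict[str, FactorNode], node: str) -> list[int]:
        """Input combination of ``node`` for every domain index."""
        specs = self.in_specs[node]
        ranks = [assignment[src].rank_of(node) for _, src, _ in specs]
        bits = []
        for kappa in self.domains:
            b = 0
            for pos, (si, _, activating) in enumerate(specs):
                above = kappa[si] > ranks[pos]
                if above == activating:
                    b |= 1 << pos
            bits.append(b)
        return bits

    def labels_for_copy(
        self, copy_fixed: dict[str, FactorNode], fg: FactorGraph
    ) -> list[MorseState]:
        """Morse-state label for every vertex of W's factor graph."""
        labels: list[MorseState] = [MorseState.OTHER] * len(fg.vertices)
        n_dom = len(self.domains)
        by_order: dict[tuple, list[int]] = {}
        for i, fn in enumerate(fg.vertices):
            by_order.setdefault(fn.order, []).append(i)
        for order, vids in by_order.items():
            rep = fg.vertices[vids[0]]
            assignment = dict(copy_fixed)
            assignment[self.w] = rep
            # flow targets of the non-query coordinates, fixed per order
            fixed_ids = tuple(
                -1
                if nd == self.w
                else self._intern(
                    tuple(assignment[nd].g[b] for b in self._bits(assignment, nd))
                )
                for nd in self.nodes
            )
            bits_w = self._bits(assignment, self.w)
            for vid in vids:
                g_w = fg.vertices[vid].g
                w_id = self._intern(tuple(g_w[b] for b in bits_w))
                key = (fixed_ids, w_id)
                state = self._memo.get(key)
                if state is None:
                    cols = [
                        self._cols[w_id if fid < 0 else fid] for fid in fixed_ids
                    ]
                    state = self._classify_table(cols)
                    self._memo[key] = state
                labels[vid] = state
        return labels

    def labels_for_copy_joint(
        self,
        copy_fixed: dict[str, FactorNode],
        fg: FactorGraph,
        chain_specs: list[tuple[str, list[FactorNode]]],
        dag: JointSignalDAG,
    ) -> list[MorseState]:
        """Morse-state label for every vertex of the joint sweep DAG.

        ``chain_specs`` lists, per swept chain node, its factor vertices in
        signal-ascending order.  Chain nodes have a single out-edge, hence
        a trivial threshold order, so only their maps vary along the sweep
        and all input-combination tables stay fixed per (copy, W-order).
        """
        labels: list[MorseState] = [MorseState.OTHER] * len(dag.verts)
        by_order: dict[tuple, list[int]] = {}
        for i, fn in enumerate(fg.vertices):
            by_order.setdefault(fn.order, []).append(i)
        chain_names = [nd for nd, _ in chain_specs]
        for order, vids in by_order.items():
            rep = fg.vertices[vids[0]]
            assignment = dict(copy_fixed)
            assignment[self.w] = rep
            for nd, fns in chain_specs:
                assignment[nd] = fns[0]
            fixed_ids = {
                nd: self._intern(
                    tuple(assignment[nd].g[b] for b in self._bits(assignment, nd))
                )
                for nd in self.nodes
                if nd != self.w and nd not in chain_names
            }
            chain_cols = {
                nd: [
                    self._intern(
                        tuple(fn.g[b] for b in self._bits(assignment, nd))
                    )
                    for fn in fns
                ]
                for nd, fns in chain_specs
            }
            bits_w = self._bits(assignment, self.w)
            w_cols = {
                vid: self._intern(
                    tuple(fg.vertices[vid].g[b] for b in bits_w)
                )
                for vid in vids
            }
            vid_set = set(vids)
            for pi, pv in enumerate(dag.verts):
                wv = pv[-1]
                if wv not in vid_set:
                    continue
                key = tuple(
                    w_cols[wv]
                    if nd == self.w
                    else chain_cols[nd][pv[chain_names.index(nd)]]
                    if nd in chain_cols
                    else fixed_ids[nd]
                    for nd in self.nodes
                )
                state = self._memo.get(key)
                if state is None:
                    state = self._classify_table([self._cols[c] for c in key])
                    self._memo[key] = state
                labels[pi] = state
        return labels

    def _classify_table(self, phi_cols: list[tuple[int, ...]]) -> MorseState:
        n_dom = len(self.domains)
        succ: list[list[int]] = []
        for di, kappa in enumerate(self.domains):
            out = []
            for ni in range(self.n):
                t = phi_cols[ni][di]
                if t > kappa[ni]:
                    out.append(di + self.strides[ni])
                elif t < kappa[ni]:
                    out.append(di - self.strides[ni])
            if not out:
                out = [di]
            succ.append(out)
        n_att, fp_idx = attractor_summary(succ)
        fp_coords = [self.domains[i][self.p_idx] for i in fp_idx]
        return _classify(n_att, fp_coords)


def compute_prevalence(
    net: RegulatoryNetwork,
    cfg: PhenotypeConfig,
    name: str | None = None,
) -> PrevalenceReport:
    """Run all phenotype path queries for one network.

    Resolves the query node W from the receiving node, enumerates the
    copies of PG(W) (essential factors for non-chain nodes when the
    essential filter is on), classifies the lifted Morse graph at every
    factor vertex of W, and counts — by automaton dynamic programming —
    how many full and partial monotone signal paths exhibit each query.
    Fully deterministic.
    """
    reduction = contract_input_chain(net, cfg.receiving_node)
    w = reduction.query_node
    fg = FactorGraph(net, w)
    chain_before = reduction.chain[:-1]
    w_fwd = SignalDAG(fg, reduction.orientation)
    # the reverse sweep, for resettability anchored at the signal-high end
    flipped = (
        Orientation.DIRECT
        if reduction.orientation is Orientation.REVERSED
        else Orientation.REVERSED
    )
    w_bwd = SignalDAG(fg, flipped)

    chain_specs: list[tuple[str, list[FactorNode]]] = []
    if cfg.sweep_chain_factors and chain_before:
        ascending = True  # the signal activates the receiving node
        prev = None
        for nd in reduction.chain:
            if prev is not None and net.edge_sign(prev, nd) is Sign.REPRESSING:
                ascending = not ascending
            if nd != w:
                fg_nd = FactorGraph(net, nd)
                fns = sorted(fg_nd.vertices, key=lambda f: sum(f.g))
                if not ascending:
                    fns = list(reversed(fns))
                chain_specs.append((nd, fns))
            prev = nd
        lengths = [len(fns) for _, fns in chain_specs]
        dag_fwd = JointSignalDAG(w_fwd, lengths)
        dag_bwd = dag_fwd.reversed()
        copies = enumerate_copies(
            net,
            w,
            chain=reduction.chain,
            essential=cfg.essential_filter,
            exclude=chain_before,
        )
    else:
        dag_fwd = w_fwd
        dag_bwd = w_bwd
        copies = enumerate_copies(
            net, w, chain=reduction.chain, essential=cfg.essential_filter
        )
    n_full = dag_fwd.n_full_paths()
    n_partial = dag_fwd.n_partial_paths()

    report = PrevalenceReport(
        network=name or " ".join(str(e) for e in net.edges),
        query_node=w,
        chain=reduction.chain,
        orientation=reduction.orientation.value,
        n_copies=len(copies),
        n_full_paths=n_full,
        n_partial_paths=n_partial,
        metadata={
            "essential_filter": cfg.essential_filter,
            "whole_path_resettable": cfg.whole_path_resettable,
            "strict_hysteresis": cfg.strict_hysteresis,
            "phenotype_node": cfg.phenotype_node,
            "chain_factors": (
                "chain factors swept jointly with the query node"
                if chain_specs
                else "all factors allowed on chain nodes, fixed per copy"
            ),
        },
    )
    for q in _QUERIES:
        for universe in ("full", "partial"):
            qc = QueryCounts()
            qc.denominator_copies = len(copies)
            qc.denominator_pairs = len(copies) * (
                n_full if universe == "full" else n_partial
            )
            report.counts[f"{q}_{universe}"] = qc
    if not copies or n_full == 0:
        report.warning = "no copies or no full paths; denominators are zero"
        return report

    automata: dict[str, tuple[Automaton, SignalDAG]] = {
        "resettable_qs": (
            resettable_automaton("QS", cfg.whole_path_resettable),
            dag_fwd,
        ),
        "resettable_ps": (
            resettable_automaton("PS", cfg.whole_path_resettable),
            dag_bwd,
        ),
        "hysteresis": (
            strict_hysteresis_automaton()
            if cfg.strict_hysteresis
            else hysteresis_automaton(),
            dag_fwd,
        ),
    }
    engine = _LabelEngine(net, cfg, w)
    # identical label vectors recur across copies; count each once
    count_cache: dict[tuple, dict[str, int]] = {}
    for copy in copies:
        if chain_specs:
            labels = engine.labels_for_copy_joint(
                dict(copy.fixed), fg, chain_specs, dag_fwd
            )
        else:
            labels = engine.labels_for_copy(dict(copy.fixed), fg)
        lkey = tuple(labels)
        hits_by_query = count_cache.get(lkey)
        if hits_by_query is None:
            hits_by_query = {}
            for q, (aut, dag) in automata.items():
                for universe in ("full", "partial"):
                    hits_by_query[f"{q}_{universe}"] = dag.count_accepted(
                        labels, aut, universe
                    )
            count_cache[lkey] = hits_by_query
        for key, hits in hits_by_query.items():
            qc = report.counts[key]
            qc.numerator_pairs += hits
            if hits:
                qc.numerator_copies += 1
    return report
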