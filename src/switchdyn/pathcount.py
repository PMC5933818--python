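"""Automaton-based counting of signal paths satisfying phenotype queries.

The monotone signal paths through a query node's factor graph form, for
each fixed threshold order, a graded DAG: vertices are the node's
monotone maps, edges raise the map by one unit at one input combination.
Full paths are the maximal chains (bottom ``g == 0`` to top ``g == T``);
partial paths are all directed unit-step chains, including constant ones
— exactly the distinct contiguous subpaths of the full paths, since every
chain extends to a maximal one.

Each phenotype query is a regular property of the path's Morse-state
label sequence, so paths are counted by dynamic programming over the
product of the DAG with a small deterministic automaton.  This gives the
same numbers as classifying every enumerated path, at polynomial instead
of exponential cost; the equivalence is exercised by the test suite on
small factor graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .network import Orientation
from .factorgraph import FactorGraph
from .queries_states import MorseState

DEAD = -1


@dataclass(frozen=True)
class Automaton:
    """Deterministic automaton over MorseState labels.

    ``start`` is entered by reading the first label (there is no epsilon
    start state: ``step(None, label)`` initializes).  ``accepting(q)``
    decides acceptance after the last label.
    """

    init: Callable[[MorseState], int]
    step: Callable[[int, MorseState], int]
    accepting: frozenset[int]


_QS_COMPAT = {MorseState.QS_MONO, MorseState.BI_QS_PS, MorseState.BI_QS_STAR}
_PS_COMPAT = {MorseState.PS_MONO, MorseState.BI_QS_PS, MorseState.BI_PS_STAR}


def resettable_automaton(reset_to: str, whole_path: bool) -> Automaton:
    """Accepts sequences exhibiting resettable (QS, PS) bistability to ``reset_to``.

    Reading direction is from the signal-withdrawn end: state 1 is a
    compatible run started by the monostable reset state, state 2 has seen
    the (QS, PS)-bistable vertex.  In whole-path mode the compatible run
    must continue through the entire sequence.
    """
    mono = MorseState.QS_MONO if reset_to == "QS" else MorseState.PS_MONO
    compat = _QS_COMPAT if reset_to == "QS" else _PS_COMPAT

    def init(label: MorseState) -> int:
        return 1 if label is mono else DEAD

    if whole_path:
        def step(q: int, label: MorseState) -> int:
            if q == DEAD or label not in compat:
                return DEAD
            if label is MorseState.BI_QS_PS:
                return 2
            return q
    else:
        def step(q: int, label: MorseState) -> int:
            if q == DEAD:
                return DEAD
            if q == 2:
                return 2
            if label is MorseState.BI_QS_PS:
                return 2
            return 1 if label in compat else DEAD

    return Automaton(init, step, frozenset({2}))


def hysteresis_automaton() -> Automaton:
    """Accepts full sweeps showing hysteresis between QS and PS.

    Phase one (states 1): a QS-compatible run opened by monostable QS;
    the first (QS, PS)-bistable vertex enters phase two.  Phase two tracks
    whether the vertices since the last bistable one have stayed
    PS-compatible (state 3), and whether the current vertex is monostable
    PS on top of that (state 4, the only accepting state).  State 2 is
    phase two with the suffix condition currently broken.
    """

    def init(label: MorseState) -> int:
        return 1 if label is MorseState.QS_MONO else DEAD

    def step(q: int, label: MorseState) -> int:
        if q == DEAD:
            return DEAD
        if q == 1:
            if label is MorseState.BI_QS_PS:
                return 3
            return 1 if label in _QS_COMPAT else DEAD
        # phase two
        if label is MorseState.BI_QS_PS:
            return 3
        if q in (3, 4):
            if label is MorseState.PS_MONO:
                return 4
            return 3 if label in _PS_COMPAT else 2
        return 2

    return Automaton(init, step, frozenset({4}))


def strict_hysteresis_automaton() -> Automaton:
    """Strict segment variant: the label sequence must be QS+ B+ PS+."""

    def init(label: MorseState) -> int:
        return 1 if label is MorseState.QS_MONO else DEAD

    def step(q: int, label: MorseState) -> int:
        if q == DEAD:
            return DEAD
        if q == 1:
            if label is MorseState.QS_MONO:
                return 1
            return 2 if label is MorseState.BI_QS_PS else DEAD
        if q == 2:
            if label is MorseState.BI_QS_PS:
                return 2
            return 3 if label is MorseState.PS_MONO else DEAD
        if q == 3:
            return 3 if label is MorseState.PS_MONO else DEAD
        return DEAD

    return Automaton(init, step, frozenset({3}))


class SignalDAG:
    """Unit-increment DAG of a factor graph, oriented by the signal.

    Vertices are factor-graph vertex ids; edges connect maps differing by
    +1 at one input combination within the same threshold order, directed
    from the signal-low end to the signal-high end (for a net-repressing
    chain the signal-low end is the *high* parameter vertex).
    """

    def __init__(self, fg: FactorGraph, orientation: Orientation):
        self.fg = fg
        self.orientation = orientation
        n = len(fg.vertices)
        asc: list[list[int]] = [[] for _ in range(n)]  # ascending g
        by_key = {(fn.g, fn.order): i for i, fn in enumerate(fg.vertices)}
        for i, fn in enumerate(fg.vertices):
            for c in range(len(fn.g)):
                if fn.g[c] < fg.n_outputs:
                    g2 = list(fn.g)
                    g2[c] += 1
                    j = by_key.get((tuple(g2), fn.order))
                    if j is not None and fg.adjacent(i, j):
                        asc[i].append(j)
        if orientation is Orientation.REVERSED:
            desc: list[list[int]] = [[] for _ in range(n)]
            for i, outs in enumerate(asc):
                for j in outs:
                    desc[j].append(i)
            self.succ = desc
            self.sources = fg.high_vertices()
            self.sinks = set(fg.low_vertices())
        else:
            self.succ = asc
            self.sources = fg.low_vertices()
            self.sinks = set(fg.high_vertices())
        # topological order: by sum of g, ascending or descending
        key = (lambda i: sum(fg.vertices[i].g))
        rev = orientation is Orientation.REVERSED
        self.topo = sorted(range(n), key=key, reverse=rev)

    # -- path totals ------------------------------------------------------

    def n_full_paths(self) -> int:
        count = [0] * len(self.succ)
        for v in self.sources:
            count[v] = 1
        for v in self.topo:
            for w in self.succ[v]:
                count[w] += count[v]
        return sum(count[v] for v in self.sinks)

    def n_partial_paths(self) -> int:
        count = [1] * len(self.succ)
        for v in self.topo:
            for w in self.succ[v]:
                count[w] += count[v]
        return sum(count)

    # -- query counting ---------------------------------------------------

    def count_accepted(
        self,
        labels: Sequence[MorseState],
        automaton: Automaton,
        universe: str,
    ) -> int:
        """Number of signal paths whose label sequence the automaton accepts.

        ``universe`` is ``"full"`` (maximal low-to-high chains) or
        ``"partial"`` (all chains, any endpoints, length >= 1).
        """
        n = len(self.succ)
        counts: list[dict[int, int]] = [dict() for _ in range(n)]

        def add(v: int, q: int, c: int) -> None:
            if q != DEAD and c:
                counts[v][q] = counts[v].get(q, 0) + c

        if universe == "partial":
            starts = range(n)
        else:
            starts = self.sources
        for v in starts:
            add(v, automaton.init(labels[v]), 1)
        for v in self.topo:
            for w in self.succ[v]:
                lw = labels[w]
                for q, c in counts[v].items():
                    add(w, automaton.step(q, lw), c)
        if universe == "partial":
            ends = range(n)
        else:
            ends = self.sinks
        total = 0
        for v in ends:
            for q, c in counts[v].items():
                if q in automaton.accepting:
                    total += c
        return total


class JointSignalDAG:
    """Signal DAG over the query node's factor graph *and* the relay chain.

    Under the joint-sweep convention the external signal drags the factor
    of every pass-through chain node along with the query node's: each
    chain node's factor graph is a path (single out-edge, at most one
    in-edge) traversed monotonically in the direction fixed by the
    cumulative edge sign, and a signal path is a monotone interleaving of
    unit steps of all swept coordinates.  Vertices are tuples
    ``(chain positions..., W vertex id)``.
    """

    def __init__(
        self,
        w_dag: SignalDAG,
        chain_lengths: Sequence[int],
    ):
        from itertools import product as iproduct

        self.w_dag = w_dag
        self.chain_lengths = tuple(chain_lengths)
        nw = len(w_dag.fg.vertices)
        self.verts: list[tuple[int, ...]] = [
            pos + (wv,)
            for pos in iproduct(*(range(m) for m in chain_lengths))
            for wv in range(nw)
        ]
        self._vid = {v: i for i, v in enumerate(self.verts)}
        k = len(chain_lengths)
        succ: list[list[int]] = [[] for _ in self.verts]
        for i, v in enumerate(self.verts):
            for c in range(k):
                if v[c] + 1 < chain_lengths[c]:
                    succ[i].append(self._vid[v[:c] + (v[c] + 1,) + v[c + 1 :]])
            for w2 in w_dag.succ[v[-1]]:
                succ[i].append(self._vid[v[:-1] + (w2,)])
        self.succ = succ
        w_rank = {}
        for rank, wv in enumerate(w_dag.topo):
            w_rank[wv] = rank
        self.topo = sorted(
            range(len(self.verts)),
            key=lambda i: sum(self.verts[i][:-1]) + w_rank[self.verts[i][-1]],
        )
        self.sources = [
            self._vid[(0,) * k + (wv,)] for wv in w_dag.sources
        ]
        top = tuple(m - 1 for m in chain_lengths)
        self.sinks = {self._vid[top + (wv,)] for wv in w_dag.sinks}

    def reversed(self) -> "JointSignalDAG":
        """The same DAG swept in the opposite signal direction."""
        rev = object.__new__(JointSignalDAG)
        rev.w_dag = self.w_dag
        rev.chain_lengths = self.chain_lengths
        rev.verts = self.verts
        rev._vid = self._vid
        succ: list[list[int]] = [[] for _ in self.verts]
        for i, outs in enumerate(self.succ):
            for j in outs:
                succ[j].append(i)
        rev.succ = succ
        rev.topo = list(reversed(self.topo))
        rev.sources = sorted(self.sinks)
        rev.sinks = set(self.sources)
        return rev

    # The counting methods are shared with SignalDAG via duck typing.
    n_full_paths = SignalDAG.n_full_paths
    n_partial_paths = SignalDAG.n_partial_paths
    count_accepted = SignalDAG.count_accepted
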