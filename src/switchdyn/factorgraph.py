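"""Factor graphs of parameter regions, the product parameter graph, and signal paths.

For each network node ``n`` with ``S`` inputs and ``T`` outputs, parameter
space decomposes into finitely many regions characterized by a pair
``(g, O)``:

* ``O`` is a total order of the node's ``T`` out-thresholds (rank 0 lowest);
* ``g`` is a monotone map from the ``2**S`` input combinations to the
  ``T + 1`` output states ``{0, ..., T}``.  Bit ``k`` of an input
  combination selects the low (0) or high (1) production contribution of
  the ``k``-th in-edge, so combination bits already absorb activation
  versus repression, and monotonicity of ``g`` is monotonicity of the
  production level in those contributions.

Two regions are adjacent when exactly one defining inequality flips:
either the orders differ by one adjacent transposition, or the orders
agree and ``g`` changes by one unit at exactly one input combination.
The parameter graph of the whole network is the product of these factor
graphs, one per node.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product
from typing import Iterator, Sequence

from .network import (
    Orientation,
    RegulatoryEdge,
    RegulatoryNetwork,
)


class CapacityError(RuntimeError):
    """Monotone-map enumeration would exceed the configured candidate cap."""


#: Default cap on (T+1)**(2**S) candidate maps before enumeration refuses.
DEFAULT_MAP_CAP = 10**6


def enumerate_monotone_maps(
    n_inputs: int, n_outputs: int, cap: int = DEFAULT_MAP_CAP
) -> list[tuple[int, ...]]:
    """All monotone maps {0,1}^n_inputs -> {0,...,n_outputs}.

    A map is returned as a tuple indexed by the input combination read as a
    binary number (bit ``k`` = the ``k``-th input).  Monotone means
    ``a <= b`` componentwise implies ``g(a) <= g(b)``.  Output order is
    lexicographic in the value tuple, hence deterministic.

    For ``n_inputs == 0`` the domain is the single empty combination and
    the result is the ``n_outputs + 1`` constant maps.
    """
    if n_inputs < 0 or n_outputs < 1:
        raise ValueError("need n_inputs >= 0 and n_outputs >= 1")
    n_comb = 1 << n_inputs
    if (n_outputs + 1) ** n_comb > cap:
        raise CapacityError(
            f"{(n_outputs + 1)}^{n_comb} candidate maps exceed cap {cap}"
        )
    # Predecessors of combination c under the bit order are c with one set
    # bit cleared; they have smaller integer index, so a left-to-right fill
    # can enforce monotonicity incrementally.
    preds = [[c & ~(1 << k) for k in range(n_inputs) if c >> k & 1] for c in range(n_comb)]
    out: list[tuple[int, ...]] = []
    g = [0] * n_comb

    def fill(c: int) -> None:
        if c == n_comb:
            out.append(tuple(g))
            return
        lo = max((g[p] for p in preds[c]), default=0)
        for v in range(lo, n_outputs + 1):
            g[c] = v
            fill(c + 1)

    fill(0)
    return out


def count_monotone_maps_bruteforce(n_inputs: int, n_outputs: int) -> int:
    """Independent oracle: filter every candidate map for monotonicity."""
    n_comb = 1 << n_inputs
    count = 0
    for values in product(range(n_outputs + 1), repeat=n_comb):
        ok = True
        for a in range(n_comb):
            for k in range(n_inputs):
                if not a >> k & 1:
                    b = a | 1 << k
                    if values[a] > values[b]:
                        ok = False
                        break
            if not ok:
                break
        if ok:
            count += 1
    return count


@dataclass(frozen=True)
class FactorNode:
    """One vertex of a node's factor graph: a (monotone map, threshold order) pair.

    ``order`` lists the targets of the node's out-edges by threshold rank
    (``order[0]`` is the lowest threshold).
    """

    node: str
    g: tuple[int, ...]
    order: tuple[str, ...]

    def rank_of(self, target: str) -> int:
        """Rank of the threshold theta_{target, node} in this order."""
        return self.order.index(target)


class FactorGraph:
    """The parameter graph PG(n) of a single network node.

    Vertices carry stable integer ids: orders are enumerated in
    lexicographic permutation order of the out-targets (declaration
    order), maps in the order of :func:`enumerate_monotone_maps`, and
    ``id = order_index * n_maps + map_index``.
    """

    def __init__(self, net: RegulatoryNetwork, node: str, cap: int = DEFAULT_MAP_CAP):
        self.net = net
        self.node = node
        self.sources = tuple(e.source for e in net.in_edges(node))
        self.targets = tuple(e.target for e in net.out_edges(node))
        self.n_inputs = len(self.sources)
        self.n_outputs = len(self.targets)
        if self.n_outputs == 0:
            raise ValueError(f"node {node!r} has no out-edge")
        self.maps = enumerate_monotone_maps(self.n_inputs, self.n_outputs, cap=cap)
        self.orders = [tuple(p) for p in permutations(self.targets)]
        self.vertices: list[FactorNode] = [
            FactorNode(node, g, order) for order in self.orders for g in self.maps
        ]
        self._index = {(fn.g, fn.order): i for i, fn in enumerate(self.vertices)}

    def __len__(self) -> int:
        return len(self.vertices)

    def index(self, fn: FactorNode) -> int:
        return self._index[(fn.g, fn.order)]

    def adjacent(self, i: int, j: int) -> bool:
        """True iff vertices i and j differ by exactly one inequality."""
        a, b = self.vertices[i], self.vertices[j]
        if a.order == b.order:
            diffs = [abs(x - y) for x, y in zip(a.g, b.g)]
            return sum(diffs) == 1 and max(diffs) == 1
        if a.g == b.g:
            return _is_adjacent_transposition(a.order, b.order)
        return False

    def edges(self) -> list[tuple[int, int]]:
        n = len(self.vertices)
        return [(i, j) for i in range(n) for j in range(i + 1, n) if self.adjacent(i, j)]

    # -- distinguished vertices and signal paths -------------------------

    def low_vertices(self) -> list[int]:
        """Vertices with g identically 0: the node is below all its thresholds."""
        return [i for i, fn in enumerate(self.vertices) if all(v == 0 for v in fn.g)]

    def high_vertices(self) -> list[int]:
        """Vertices with g identically T: the node is above all its thresholds."""
        T = self.n_outputs
        return [i for i, fn in enumerate(self.vertices) if all(v == T for v in fn.g)]

    def full_paths(self, orientation: Orientation = Orientation.DIRECT) -> list[tuple[int, ...]]:
        """All monotone full paths: low to high, threshold order held fixed.

        Each step raises ``g`` by one unit at exactly one input combination,
        so every full path over an order with S inputs and T outputs has
        ``T * 2**S`` steps.  For ``orientation == REVERSED`` each path is
        reported from the high vertex to the low vertex (the signal then
        acts through a net repression, interchanging the roles of the
        lowest and highest parameter nodes).
        """
        T = self.n_outputs
        n_comb = 1 << self.n_inputs
        paths: list[tuple[int, ...]] = []

        def extend(order: tuple[str, ...], g: list[int], acc: list[int]) -> None:
            if all(v == T for v in g):
                paths.append(tuple(acc))
                return
            for c in range(n_comb):
                if g[c] == T:
                    continue
                g2 = list(g)
                g2[c] += 1
                if _is_monotone(g2, self.n_inputs):
                    acc.append(self._index[(tuple(g2), order)])
                    extend(order, g2, acc)
                    acc.pop()

        for order in self.orders:
            g0 = [0] * n_comb
            start = self._index[(tuple(g0), order)]
            extend(order, g0, [start])
        if orientation is Orientation.REVERSED:
            paths = [tuple(reversed(p)) for p in paths]
        return paths


def _is_monotone(g: Sequence[int], n_inputs: int) -> bool:
    for a in range(len(g)):
        for k in range(n_inputs):
            if not a >> k & 1 and g[a] > g[a | 1 << k]:
                return False
    return True


def _is_adjacent_transposition(a: Sequence[str], b: Sequence[str]) -> bool:
    diff = [r for r, (x, y) in enumerate(zip(a, b)) if x != y]
    return (
        len(diff) == 2
        and diff[1] == diff[0] + 1
        and a[diff[0]] == b[diff[1]]
        and a[diff[1]] == b[diff[0]]
    )


def low_and_high_nodes(fg: FactorGraph) -> tuple[list[int], list[int]]:
    """(lows, highs): vertices with g identically 0 / identically T.

    These are sets, one per threshold order; a unique lowest/highest
    vertex exists only for T = 1.
    """
    return fg.low_vertices(), fg.high_vertices()


def enumerate_full_paths(
    fg: FactorGraph, orientation: Orientation = Orientation.DIRECT
) -> list[tuple[int, ...]]:
    """All monotone full paths of ``fg`` (see :meth:`FactorGraph.full_paths`)."""
    return fg.full_paths(orientation)


def enumerate_partial_paths(full_paths: Sequence[Sequence[int]]) -> list[tuple[int, ...]]:
    """All distinct contiguous subsequences (length >= 1) of the full paths.

    Subpaths keep the direction of their parent full path; a subpath and
    its reversal count as one path (the stored representative is the
    parent's direction).  Constant (single-vertex) paths are included.
    """
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    for path in full_paths:
        m = len(path)
        for i in range(m):
            for j in range(i, m):
                sub = tuple(path[i : j + 1])
                key = min(sub, tuple(reversed(sub)))
                if key not in seen:
                    seen.add(key)
                    out.append(sub)
    return out


# ---------------------------------------------------------------------------
# Assignments, essentiality, copies


#: A parameter-graph vertex: one FactorNode per network node.
FactorAssignment = dict[str, FactorNode]


def build_factor_graph(net: RegulatoryNetwork, node: str, cap: int = DEFAULT_MAP_CAP) -> FactorGraph:
    return FactorGraph(net, node, cap=cap)


def factor_graphs(net: RegulatoryNetwork, cap: int = DEFAULT_MAP_CAP) -> dict[str, FactorGraph]:
    return {n: FactorGraph(net, n, cap=cap) for n in net.nodes}


def parameter_graph_size(net: RegulatoryNetwork) -> int:
    """|PG| = prod_n |PG(n)| (the parameter graph is a product graph)."""
    size = 1
    for n in net.nodes:
        size *= len(FactorGraph(net, n))
    return size


def enumerate_assignments(net: RegulatoryNetwork) -> Iterator[FactorAssignment]:
    """Every vertex of the product parameter graph, in deterministic order."""
    fgs = factor_graphs(net)
    names = net.nodes
    for combo in product(*(fgs[n].vertices for n in names)):
        yield dict(zip(names, combo))


def _input_bit_position(net: RegulatoryNetwork, target: str, source: str) -> int:
    sources = tuple(e.source for e in net.in_edges(target))
    return sources.index(source)


def edge_essentiality(
    net: RegulatoryNetwork, assignment: FactorAssignment, edge: RegulatoryEdge
) -> tuple[bool, bool]:
    """(input_essential, output_essential) of ``edge`` at ``assignment``.

    Input-essential: flipping only this edge's input bit changes the
    target's map for some combination, i.e. the edge actually influences
    its target.  Output-essential: the source's map attains values on both
    sides of this edge's threshold, i.e. the source actually crosses it.
    """
    g_target = assignment[edge.target].g
    k = _input_bit_position(net, edge.target, edge.source)
    n_in = net.n_inputs(edge.target)
    input_essential = any(
        g_target[c] != g_target[c | 1 << k]
        for c in range(1 << n_in)
        if not c >> k & 1
    )
    src_fn = assignment[edge.source]
    rank = src_fn.rank_of(edge.target)
    g_src = src_fn.g
    output_essential = min(g_src) <= rank and max(g_src) >= rank + 1
    return input_essential, output_essential


def factor_is_essential(net: RegulatoryNetwork, node: str, fn: FactorNode) -> bool:
    """Local essentiality of one node's factor.

    Both halves of the edge-essentiality definition are local to a single
    node's (g, O): input-essentiality of an in-edge depends only on the
    target's map, output-essentiality of an out-edge only on the source's
    map and order.  Essentiality of a full parameter node therefore
    factorizes over the network nodes.
    """
    n_in = net.n_inputs(node)
    for k in range(n_in):
        if not any(
            fn.g[c] != fn.g[c | 1 << k] for c in range(1 << n_in) if not c >> k & 1
        ):
            return False
    for e in net.out_edges(node):
        rank = fn.rank_of(e.target)
        if not (min(fn.g) <= rank and max(fn.g) >= rank + 1):
            return False
    return True


def is_essential_assignment(net: RegulatoryNetwork, assignment: FactorAssignment) -> bool:
    """True iff every edge is input- and output-essential at ``assignment``."""
    return all(factor_is_essential(net, n, assignment[n]) for n in net.nodes)


def essential_vertices(net: RegulatoryNetwork, fg: FactorGraph) -> list[int]:
    return [i for i, fn in enumerate(fg.vertices) if factor_is_essential(net, fg.node, fn)]


@dataclass(frozen=True)
class CopyHandle:
    """One copy G of PG(W) inside the product graph: fixed factors for all
    nodes except the query node W.  ``assignment_for`` lifts a factor
    vertex of W to the corresponding full parameter-graph vertex; a path
    in PG(W) lifts vertex-wise to a path in G.
    """

    query_node: str
    fixed: tuple[tuple[str, "FactorNode"], ...]

    def assignment_for(self, w_factor: FactorNode) -> FactorAssignment:
        a = dict(self.fixed)
        a[self.query_node] = w_factor
        return a


def enumerate_copies(
    net: RegulatoryNetwork,
    query_node: str,
    chain: Sequence[str] = (),
    essential: bool = True,
    cap: int = DEFAULT_MAP_CAP,
    exclude: Sequence[str] = (),
) -> list[CopyHandle]:
    """The copies of PG(W): assignments of factors to every node except W.

    With ``essential=True`` every node outside the signal chain is
    restricted to its essential factor vertices; chain nodes (pure signal
    relays upstream of W) keep all their factors, since the relay of an
    external signal is inessential by construction (a relay head has no
    inputs, so its out-edge can never be output-essential).  The order of
    copies is deterministic: nodes in declaration order, factor vertices
    by id.
    """
    chain_set = set(chain)
    excluded = set(exclude) | {query_node}
    others = [n for n in net.nodes if n not in excluded]
    choice_lists: list[list[FactorNode]] = []
    for n in others:
        fg = FactorGraph(net, n, cap=cap)
        if essential and n not in chain_set:
            idxs = essential_vertices(net, fg)
        else:
            idxs = list(range(len(fg)))
        choice_lists.append([fg.vertices[i] for i in idxs])
    copies = []
    for combo in product(*choice_lists):
        copies.append(CopyHandle(query_node, tuple(zip(others, combo))))
    return copies
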