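"""State transition graphs on threshold-delimited domains and their Morse graphs.

At a fixed parameter-graph vertex, phase space splits into rectangular
domains, one per integer vector ``kappa`` with ``kappa_n`` counting how
many of node ``n``'s own out-thresholds lie below ``x_n``.  The flow
direction across each wall is parameter-determined, yielding a finite
directed graph on domains; its recurrent components, condensed and
partially ordered by reachability, form the Morse graph.  Minimal Morse
nodes are the attractors; a singleton component whose only edge is a
self-edge is labeled ``FP(kappa)`` and plays the role of a stable
equilibrium inside that domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import networkx as nx

from .network import RegulatoryNetwork, Sign
from .factorgraph import FactorAssignment

Domain = tuple[int, ...]


def enumerate_domains(net: RegulatoryNetwork) -> list[Domain]:
    """All prod_n (T_n + 1) domains, lexicographic in declaration order."""
    ranges = [range(net.n_outputs(n) + 1) for n in net.nodes]
    return [tuple(k) for k in product(*ranges)]


def input_combination(
    net: RegulatoryNetwork, assignment: FactorAssignment, node: str, kappa: Domain
) -> int:
    """The input combination (as a bit vector) seen by ``node`` in domain ``kappa``.

    For in-edge ``k -> node``, let ``r`` be the rank of the threshold
    ``theta_{node,k}`` in node k's threshold order; ``x_k`` is above that
    threshold iff ``kappa_k > r``.  An activating edge selects the high
    contribution when above, a repressing edge when below.
    """
    bits = 0
    for pos, e in enumerate(net.in_edges(node)):
        src_fn = assignment[e.source]
        r = src_fn.rank_of(node)
        above = kappa[net.node_index(e.source)] > r
        high = above if e.sign is Sign.ACTIVATING else not above
        if high:
            bits |= 1 << pos
    return bits


def target_state(
    net: RegulatoryNetwork, assignment: FactorAssignment, kappa: Domain
) -> Domain:
    """Phi(kappa): where the flow in each coordinate is headed.

    Coordinate ``n`` of the target is the value of node n's monotone map at
    the input combination induced by ``kappa``; the flow in ``x_n`` points
    from ``kappa_n`` toward ``Phi(kappa)_n``.
    """
    return tuple(
        assignment[n].g[input_combination(net, assignment, n, kappa)]
        for n in net.nodes
    )


@dataclass
class StateTransitionGraph:
    """Directed graph on domains; ``succ[kappa]`` lists the out-neighbors
    (a domain with target equal to itself carries a self-edge)."""

    net: RegulatoryNetwork
    domains: list[Domain]
    succ: dict[Domain, list[Domain]]

    def has_self_edge(self, kappa: Domain) -> bool:
        return kappa in self.succ[kappa]

    def n_edges(self) -> int:
        return sum(len(v) for v in self.succ.values())

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.domains)
        for k, vs in self.succ.items():
            g.add_edges_from((k, v) for v in vs)
        return g


def build_state_transition_graph(
    net: RegulatoryNetwork, assignment: FactorAssignment
) -> StateTransitionGraph:
    """Domain graph: an edge ``kappa -> kappa +/- e_n`` whenever the flow in
    coordinate ``n`` points that way, and a self-edge iff Phi(kappa) = kappa."""
    domains = enumerate_domains(net)
    succ: dict[Domain, list[Domain]] = {}
    for kappa in domains:
        phi = target_state(net, assignment, kappa)
        out: list[Domain] = []
        for n in range(len(kappa)):
            if phi[n] > kappa[n]:
                out.append(kappa[:n] + (kappa[n] + 1,) + kappa[n + 1 :])
            elif phi[n] < kappa[n]:
                out.append(kappa[:n] + (kappa[n] - 1,) + kappa[n + 1 :])
        if not out:
            out = [kappa]
        succ[kappa] = out
    return StateTransitionGraph(net, domains, succ)


@dataclass(frozen=True)
class MorseNode:
    """One recurrent component; ``fp_label`` is set iff the component is a
    single domain with a self-edge (the combinatorial stable equilibrium)."""

    domains: frozenset[Domain]
    fp_label: Domain | None

    @property
    def is_fp(self) -> bool:
        return self.fp_label is not None

    def __str__(self) -> str:
        if self.is_fp:
            return "FP(" + ", ".join(map(str, self.fp_label)) + ")"
        return "RC{" + ", ".join(map(str, sorted(self.domains))) + "}"


@dataclass
class MorseGraph:
    """Condensation of the STG's recurrent components.

    ``order`` holds pairs ``(i, j)`` meaning node i lies above node j
    (some STG path leads from component i into component j).  Minimal
    nodes — no outgoing order relation — are the attractors.
    """

    nodes: list[MorseNode]
    order: set[tuple[int, int]]

    def minimal_nodes(self) -> list[int]:
        above = {i for i, _ in self.order}
        return [i for i in range(len(self.nodes)) if i not in above]

    def attractors(self) -> list[MorseNode]:
        return [self.nodes[i] for i in self.minimal_nodes()]

    def fp_attractors(self) -> list[Domain]:
        return [m.fp_label for m in self.attractors() if m.is_fp]


def build_morse_graph(stg: StateTransitionGraph) -> MorseGraph:
    """Condense the STG: recurrent SCCs (those containing an edge) become
    Morse nodes, partially ordered by reachability."""
    g = stg.to_networkx()
    comp_of: dict[Domain, int] = {}
    sccs = list(nx.strongly_connected_components(g))
    recurrent: list[frozenset[Domain]] = []
    for scc in sccs:
        members = frozenset(scc)
        if len(members) > 1 or stg.has_self_edge(next(iter(members))):
            recurrent.append(members)
    # stable order for reproducibility
    recurrent.sort(key=lambda ms: sorted(ms)[0])
    nodes = []
    for members in recurrent:
        fp = None
        if len(members) == 1:
            (kappa,) = members
            if stg.succ[kappa] == [kappa]:
                fp = kappa
        nodes.append(MorseNode(members, fp))

    cond = nx.condensation(g)
    scc_id_of_domain = {d: cid for cid, data in cond.nodes(data=True) for d in data["members"]}
    reach = {cid: nx.descendants(cond, cid) for cid in cond.nodes}
    order: set[tuple[int, int]] = set()
    for i, mi in enumerate(nodes):
        ci = scc_id_of_domain[next(iter(mi.domains))]
        for j, mj in enumerate(nodes):
            if i == j:
                continue
            cj = scc_id_of_domain[next(iter(mj.domains))]
            if cj in reach[ci]:
                order.add((i, j))
    return MorseGraph(nodes, order)


def morse_graph(net: RegulatoryNetwork, assignment: FactorAssignment) -> MorseGraph:
    """Convenience: STG construction followed by condensation."""
    return build_morse_graph(build_state_transition_graph(net, assignment))


# ---------------------------------------------------------------------------
# Index-based fast path (used by the prevalence engine)


def attractor_summary(succ: list[list[int]]) -> tuple[int, list[int]]:
    """Attractors of an index-based STG: (count, fixed-point vertex indices).

    ``succ[i]`` lists out-neighbors of vertex ``i`` (a self-loop marks a
    fixed domain).  Recurrent SCCs are those containing an edge; an
    attractor is a recurrent SCC from which no other recurrent SCC is
    reachable.  Returns the number of attractors and the indices of those
    that are singleton self-loop components (combinatorial fixed points).

    Iterative Tarjan; emits SCCs sinks-first, which makes the
    reaches-a-recurrent-component flag a single backward pass.
    """
    n = len(succ)
    index = [0] * n
    low = [0] * n
    on_stack = [False] * n
    comp = [-1] * n
    visited = [False] * n
    stack: list[int] = []
    sccs: list[list[int]] = []
    counter = 1

    for root in range(n):
        if visited[root]:
            continue
        work = [(root, 0)]
        while work:
            v, pi = work[-1]
            if pi == 0:
                visited[v] = True
                index[v] = low[v] = counter
                counter += 1
                stack.append(v)
                on_stack[v] = True
            recurse = False
            for i in range(pi, len(succ[v])):
                w = succ[v][i]
                if not visited[w]:
                    work[-1] = (v, i + 1)
                    work.append((w, 0))
                    recurse = True
                    break
                if on_stack[w]:
                    low[v] = min(low[v], index[w])
            if recurse:
                continue
            work.pop()
            if low[v] == index[v]:
                members = []
                while True:
                    w = stack.pop()
                    on_stack[w] = False
                    comp[w] = len(sccs)
                    members.append(w)
                    if w == v:
                        break
                sccs.append(members)
            if work:
                u, _ = work[-1]
                low[u] = min(low[u], low[v])

    n_scc = len(sccs)
    recurrent = [False] * n_scc
    for cid, members in enumerate(sccs):
        if len(members) > 1:
            recurrent[cid] = True
        else:
            v = members[0]
            recurrent[cid] = v in succ[v]
    # Tarjan order: sccs[k] emitted before any SCC that can reach it, so a
    # forward pass over k sees all successors already processed.
    reaches_rec = [False] * n_scc
    for cid in range(n_scc):
        flag = False
        for v in sccs[cid]:
            for w in succ[v]:
                d = comp[w]
                if d != cid and (recurrent[d] or reaches_rec[d]):
                    flag = True
                    break
            if flag:
                break
        reaches_rec[cid] = flag
    n_attractors = 0
    fp_indices: list[int] = []
    for cid in range(n_scc):
        if recurrent[cid] and not reaches_rec[cid]:
            n_attractors += 1
            if len(sccs[cid]) == 1:
                v = sccs[cid][0]
                if succ[v] == [v]:
                    fp_indices.append(v)
    return n_attractors, fp_indices


# ---------------------------------------------------------------------------
# Brute-force oracle used by the test suite


def recurrent_components_bruteforce(
    domains: Sequence[Domain], succ: dict[Domain, Iterable[Domain]]
) -> list[frozenset[Domain]]:
    """Reachability-closure oracle for recurrent components.

    Computes full transitive reachability by iterated expansion, then
    groups mutually reachable vertices and keeps groups containing at
    least one edge.  Quadratic-ish and independent of the SCC algorithm
    used by :func:`build_morse_graph`.
    """
    reach: dict[Domain, set[Domain]] = {d: set(succ[d]) for d in domains}
    changed = True
    while changed:
        changed = False
        for d in domains:
            new = set()
            for e in reach[d]:
                new |= reach[e]
            if not new <= reach[d]:
                reach[d] |= new
                changed = True
    comps: list[frozenset[Domain]] = []
    assigned: set[Domain] = set()
    for d in domains:
        if d in assigned:
            continue
        comp = frozenset(
            e for e in domains if e == d or (e in reach[d] and d in reach[e])
        )
        assigned |= comp
        has_internal_edge = any(v in comp for m in comp for v in succ[m])
        if has_internal_edge:
            comps.append(comp)
    return comps
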