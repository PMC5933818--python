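"""Regulatory networks: parsing, validation, templates, and input-chain reduction.

A regulatory network is a signed directed graph.  Each edge ``j -> i``
(activation) or ``j ~> i`` (repression, drawn elsewhere as ``j -| i``) carries
one threshold; each node combines its in-edges through an AND-of-OR logic
tree.  Two admissibility rules apply throughout the package: every node has
at least one out-edge, and there is at most one edge per ordered node pair.

The plain-text format is one line per node::

    name : (term + term)(term)...

where a parenthesized group is one AND-factor, ``+`` separates OR-terms
inside a factor, and a ``~`` prefix marks a repressing input.  ``#`` starts
a comment.  A node with no inputs is written ``name :`` with an empty
right-hand side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class Sign(str, Enum):
    """Sign of a regulatory interaction."""

    ACTIVATING = "activating"
    REPRESSING = "repressing"

    def __invert__(self) -> "Sign":
        return Sign.REPRESSING if self is Sign.ACTIVATING else Sign.ACTIVATING


@dataclass(frozen=True, order=True)
class RegulatoryEdge:
    """A signed edge ``source -> target`` (or ``source ~> target``)."""

    source: str
    target: str
    sign: Sign

    def __str__(self) -> str:
        arrow = "->" if self.sign is Sign.ACTIVATING else "~>"
        return f"{self.source} {arrow} {self.target}"


class NetworkFormatError(ValueError):
    """Raised when a network file violates the grammar or references unknown nodes."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# A logic tree is a tuple of AND-factors, each factor a tuple of source names
# (OR within the factor).  Signs live on the edges, not in the tree.
LogicTree = tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class RegulatoryNetwork:
    """An admissible (or to-be-validated) regulatory network.

    ``nodes`` fixes the coordinate order used by every domain vector,
    fixed-point label, and printed tuple in the package.
    """

    nodes: tuple[str, ...]
    edges: tuple[RegulatoryEdge, ...]
    logic: dict[str, LogicTree] = field(compare=False)

    # -- derived structure ------------------------------------------------

    def node_index(self, name: str) -> int:
        return self.nodes.index(name)

    def edge_sign(self, source: str, target: str) -> Sign:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e.sign
        raise KeyError(f"no edge {source} -> {target}")

    def has_edge(self, source: str, target: str) -> bool:
        return any(e.source == source and e.target == target for e in self.edges)

    def in_edges(self, node: str) -> tuple[RegulatoryEdge, ...]:
        """In-edges of ``node``, ordered by declaration order of the source."""
        es = [e for e in self.edges if e.target == node]
        es.sort(key=lambda e: self.node_index(e.source))
        return tuple(es)

    def out_edges(self, node: str) -> tuple[RegulatoryEdge, ...]:
        """Out-edges of ``node``, ordered by declaration order of the target."""
        es = [e for e in self.edges if e.source == node]
        es.sort(key=lambda e: self.node_index(e.target))
        return tuple(es)

    def n_inputs(self, node: str) -> int:
        """S_n: the in-degree of ``node`` (self-edges count)."""
        return len(self.in_edges(node))

    def n_outputs(self, node: str) -> int:
        """T_n: the out-degree of ``node``, i.e. its number of thresholds."""
        return len(self.out_edges(node))

    # -- text format ------------------------------------------------------

    def serialize(self) -> str:
        """Canonical text form; ``parse_network`` round-trips it."""
        lines = []
        for n in self.nodes:
            factors = []
            for factor in self.logic[n]:
                terms = []
                for src in factor:
                    prefix = "~" if self.edge_sign(src, n) is Sign.REPRESSING else ""
                    terms.append(prefix + src)
                factors.append("(" + " + ".join(terms) + ")")
            lines.append(f"{n} : " + "".join(factors) if factors else f"{n} :")
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        return self.serialize()


_NODE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _strip_comment(line: str) -> str:
    return line.split("#", 1)[0]


def parse_network(text: str) -> RegulatoryNetwork:
    """Parse the plain-text network format into a :class:`RegulatoryNetwork`.

    Declaration order of the node lines fixes the coordinate order.  Raises
    :class:`NetworkFormatError` on grammar violations, unknown node names,
    duplicate ordered edges, or a node with no out-edge.
    """
    nodes: list[str] = []
    raw_logic: dict[str, list[list[tuple[str, Sign]]]] = {}
    line_of: dict[str, int] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        if ":" not in line:
            raise NetworkFormatError("expected 'name : factors'", lineno)
        name, rhs = (part.strip() for part in line.split(":", 1))
        if not _NODE_RE.match(name):
            raise NetworkFormatError(f"invalid node name {name!r}", lineno)
        if name in raw_logic:
            raise NetworkFormatError(f"node {name!r} declared twice", lineno)
        nodes.append(name)
        line_of[name] = lineno
        raw_logic[name] = _parse_factors(rhs, lineno)

    edges: list[RegulatoryEdge] = []
    logic: dict[str, LogicTree] = {}
    seen_pairs: set[tuple[str, str]] = set()
    for name in nodes:
        factors: list[tuple[str, ...]] = []
        for factor in raw_logic[name]:
            terms = []
            for src, sign in factor:
                if src not in raw_logic:
                    raise NetworkFormatError(
                        f"unknown node {src!r} in logic of {name!r}", line_of[name]
                    )
                if (src, name) in seen_pairs:
                    raise NetworkFormatError(
                        f"duplicate edge {src} -> {name}", line_of[name]
                    )
                seen_pairs.add((src, name))
                edges.append(RegulatoryEdge(src, name, sign))
                terms.append(src)
            factors.append(tuple(terms))
        logic[name] = tuple(factors)

    net = RegulatoryNetwork(tuple(nodes), tuple(edges), logic)
    problems = validate_network(net)
    if problems:
        raise NetworkFormatError("; ".join(problems))
    return net


def _parse_factors(rhs: str, lineno: int) -> list[list[tuple[str, Sign]]]:
    rhs = rhs.strip()
    if not rhs:
        return []
    factors: list[list[tuple[str, Sign]]] = []
    pos = 0
    while pos < len(rhs):
        if rhs[pos].isspace():
            pos += 1
            continue
        if rhs[pos] != "(":
            raise NetworkFormatError(f"expected '(' at column {pos + 1}", lineno)
        close = rhs.find(")", pos)
        if close < 0:
            raise NetworkFormatError("unbalanced parenthesis", lineno)
        inner = rhs[pos + 1 : close]
        terms = []
        for piece in inner.split("+"):
            piece = piece.strip()
            if not piece:
                raise NetworkFormatError("empty term", lineno)
            sign = Sign.ACTIVATING
            if piece.startswith("~"):
                sign = Sign.REPRESSING
                piece = piece[1:].strip()
            if not _NODE_RE.match(piece):
                raise NetworkFormatError(f"invalid term {piece!r}", lineno)
            terms.append((piece, sign))
        factors.append(terms)
        pos = close + 1
    return factors


def validate_network(net: RegulatoryNetwork) -> list[str]:
    """Return admissibility violations (empty list means admissible).

    The two rules checked are the standing assumptions of the whole
    framework: every node has at least one out-edge, and there is at most
    one edge per ordered node pair.
    """
    problems = []
    pairs: dict[tuple[str, str], int] = {}
    for e in net.edges:
        pairs[(e.source, e.target)] = pairs.get((e.source, e.target), 0) + 1
    for (s, t), count in pairs.items():
        if count > 1:
            problems.append(f"multiple edges for ordered pair ({s}, {t})")
    for n in net.nodes:
        if net.n_outputs(n) == 0:
            problems.append(f"node {n!r} has no outgoing edge")
    return problems


def network_from_edges(
    nodes: Sequence[str],
    edges: Sequence[RegulatoryEdge],
    logic: dict[str, LogicTree] | None = None,
) -> RegulatoryNetwork:
    """Assemble a network from an explicit edge list.

    When ``logic`` is omitted each in-edge becomes its own AND-factor
    (pure product logic), the default used for screened subnetworks.
    """
    nodes = tuple(nodes)
    if logic is None:
        logic = {}
        for n in nodes:
            ins = sorted(
                (e.source for e in edges if e.target == n),
                key=lambda s: nodes.index(s),
            )
            logic[n] = tuple((src,) for src in ins)
    return RegulatoryNetwork(nodes, tuple(sorted(edges, key=lambda e: (nodes.index(e.source), nodes.index(e.target)))), logic)


# ---------------------------------------------------------------------------
# Templates


@dataclass(frozen=True)
class NetworkTemplate:
    """A base edge set plus optional edges, for subnetwork screening."""

    nodes: tuple[str, ...]
    base_edges: tuple[RegulatoryEdge, ...]
    optional_edges: tuple[RegulatoryEdge, ...]

    def __post_init__(self):
        base_pairs = {(e.source, e.target) for e in self.base_edges}
        for e in self.optional_edges:
            if (e.source, e.target) in base_pairs:
                raise ValueError(f"optional edge {e} duplicates a base edge pair")


def parse_template(text: str) -> NetworkTemplate:
    """Parse a template file: a network section, then ``[optional]`` edges.

    Optional edge lines read ``source -> target`` (activating) or
    ``source ~> target`` (repressing).
    """
    if "[optional]" in text:
        head, tail = text.split("[optional]", 1)
    else:
        head, tail = text, ""
    # The base section need not be admissible on its own, so parse leniently.
    base = _parse_fragment(head)
    optional: list[RegulatoryEdge] = []
    for lineno, raw in enumerate(tail.splitlines(), start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        m = re.match(r"^(\w+)\s*(~?->|~>)\s*(\w+)$", line)
        if not m:
            raise NetworkFormatError(f"bad optional edge {line!r}")
        src, arrow, tgt = m.groups()
        sign = Sign.ACTIVATING if arrow == "->" else Sign.REPRESSING
        if src not in base.nodes or tgt not in base.nodes:
            raise NetworkFormatError(f"optional edge {line!r} uses undeclared node")
        optional.append(RegulatoryEdge(src, tgt, sign))
    return NetworkTemplate(base.nodes, base.edges, tuple(optional))


def _parse_fragment(text: str) -> RegulatoryNetwork:
    """Parse node lines without enforcing admissibility (templates only)."""
    nodes: list[str] = []
    raw_logic: dict[str, list[list[tuple[str, Sign]]]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        name, rhs = (part.strip() for part in line.split(":", 1))
        nodes.append(name)
        raw_logic[name] = _parse_factors(rhs, lineno)
    edges = []
    for name in nodes:
        for factor in raw_logic[name]:
            for src, sign in factor:
                edges.append(RegulatoryEdge(src, name, sign))
    return network_from_edges(nodes, edges)


def enumerate_template_subnetworks(tmpl: NetworkTemplate) -> list[RegulatoryNetwork]:
    """All admissible subnetworks: base edges plus a subset of optional edges.

    Every template node is kept.  Subsets are visited in lexicographic order
    of the included-edge bitmask (bit ``k`` = ``tmpl.optional_edges[k]``), so
    the output order is deterministic and reproducible.
    """
    result = []
    m = len(tmpl.optional_edges)
    for mask in range(2**m):
        chosen = [tmpl.optional_edges[k] for k in range(m) if mask >> k & 1]
        edges = list(tmpl.base_edges) + chosen
        pairs = [(e.source, e.target) for e in edges]
        if len(set(pairs)) != len(pairs):
            continue
        net = network_from_edges(tmpl.nodes, edges)
        if not validate_network(net):
            result.append(net)
    return result


# ---------------------------------------------------------------------------
# Input-chain reduction


class Orientation(str, Enum):
    """Net sign of the signal chain: reversed iff an odd number of repressions."""

    DIRECT = "direct"
    REVERSED = "reversed"


@dataclass(frozen=True)
class InputChainReduction:
    """Resolution of the external signal's entry point to the query node W.

    The external signal S acts on ``chain[0]`` (the receiving node).  While
    the current node merely relays the signal (a single out-edge, no in-edge
    other than the chain itself), the walk advances; W is the first node
    with more than one input or more than one output.  The signal is then
    modeled as monotone paths through W's factor graph; ``orientation`` is
    reversed iff the relayed signal acts on W through an odd number of
    repressing edges.
    """

    query_node: str
    chain: tuple[str, ...]
    orientation: Orientation


class ChainReductionError(ValueError):
    pass


def contract_input_chain(net: RegulatoryNetwork, receiving_node: str) -> InputChainReduction:
    """Walk the signal chain from ``receiving_node`` to the query node W."""
    if receiving_node not in net.nodes:
        raise KeyError(f"unknown node {receiving_node!r}")
    chain = [receiving_node]
    n_repressions = 0
    current = receiving_node
    prev: str | None = None
    while True:
        outs = net.out_edges(current)
        other_ins = [e for e in net.in_edges(current) if e.source != prev]
        if len(outs) > 1 or other_ins:
            # current is W: it has >1 output, or an input beside the chain
            # (for the receiving node itself, any input at all).
            break
        # current is a pure relay; advance along its unique out-edge.
        step = outs[0]
        if step.target in chain:
            raise ChainReductionError(
                f"signal chain revisits node {step.target!r} (pass-through cycle)"
            )
        if step.sign is Sign.REPRESSING:
            n_repressions += 1
        prev = current
        current = step.target
        chain.append(current)
    orientation = Orientation.REVERSED if n_repressions % 2 else Orientation.DIRECT
    return InputChainReduction(current, tuple(chain), orientation)
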