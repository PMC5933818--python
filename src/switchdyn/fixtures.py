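"""Case-study networks: toggle switch, E2F-Rb restriction point, yeast START.

All networks here are transcribed from published network diagrams of the
mammalian restriction point (the coarse-grained Myc/CycD - Rb - E2F
system and its 5/6-node refinements) and the budding-yeast START circuit.
The 3-node edge template is cross-checked by the screening count: exactly
49 admissible subnetworks retain all three nodes with at least one
out-edge each.
"""

from __future__ import annotations

from .network import (
    NetworkTemplate,
    RegulatoryEdge,
    RegulatoryNetwork,
    Sign,
    network_from_edges,
    parse_network,
    parse_template,
)

#: The mutual-repression toggle switch.
TOGGLE_TEXT = """\
x1 : (~x2)
x2 : (~x1)
"""


def toggle_switch() -> RegulatoryNetwork:
    return parse_network(TOGGLE_TEXT)


#: 3-node E2F-Rb restriction-point template.  Nodes: MD (Myc/CycD, the
#: signal-receiving node), RP (Rb), EE (free E2F).  Rb's sequestration of
#: E2F (RP -| EE) is present in every subnetwork; the remaining regulatory
#: arms — Rb phosphorylation by MD and by EE's cyclin activity, E2F
#: transcriptional self-amplification, and the growth-module feedbacks —
#: are optional.
E2F_RB_TEMPLATE_TEXT = """\
MD :
RP :
EE : (~RP)
[optional]
MD ~> RP
MD -> EE
MD -> MD
EE ~> RP
EE -> MD
EE -> EE
"""


def e2f_rb_template() -> NetworkTemplate:
    return parse_template(E2F_RB_TEMPLATE_TEXT)


#: The top-ranked 3-node restriction-point subnetwork under the strict
#: hysteresis screen: all full signal paths are hysteretic.  It is the
#: 3-node core shared with the yeast START circuit (growth module
#: represses Rb, Rb sequesters E2F, E2F's cyclin activity represses Rb).
E2F_RB_TOP_TEXT = """\
MD :
RP : (~MD)(~EE)
EE : (~RP)
"""


def e2f_rb_top() -> RegulatoryNetwork:
    """Top-ranked screened 3-node network (all full paths hysteretic)."""
    return parse_network(E2F_RB_TOP_TEXT)


#: The fifth-ranked 3-node subnetwork by partial-path hysteresis: the
#: E2F -> growth-module feedback loop variant.
E2F_RB_FIFTH_TEXT = """\
MD : (EE)
RP : (~MD)
EE : (~RP)
"""


def e2f_rb_fifth() -> RegulatoryNetwork:
    """Fifth-ranked screened 3-node network."""
    return parse_network(E2F_RB_FIFTH_TEXT)


#: Yeast cell-cycle initiation (START) network: Cln3 -| Whi5 -| SBF -> Cln2 -| Whi5.
START_TEXT = """\
Cln3 :
Whi5 : (~Cln3)(~Cln2)
SBF : (~Whi5)
Cln2 : (SBF)
"""


def start_network() -> RegulatoryNetwork:
    return parse_network(START_TEXT)


#: Best 5-node mammalian restriction-point network: the START topology with
#: the growth module split into Myc -> CycD.
FIVE_NODE_BEST_TEXT = """\
Myc :
CycD : (Myc)
Rb : (~CycD)(~CycE)
E2F : (~Rb)
CycE : (E2F)
"""


def five_node_best() -> RegulatoryNetwork:
    return parse_network(FIVE_NODE_BEST_TEXT)


#: 5-node variants: the mandatory edges above plus any subset of {2a, 2b}
#: and at most one of {7, 8}.  Edge labels follow the screened family:
#: 2a = Myc -> E2F, 2b = CycD -> E2F (E2F up-regulation by the growth
#: module), 7 = E2F -> Myc, 8 = CycE -> Myc (proliferative feedback onto
#: the growth module).
_FIVE_NODE_OPTIONAL = {
    "2a": RegulatoryEdge("Myc", "E2F", Sign.ACTIVATING),
    "2b": RegulatoryEdge("CycD", "E2F", Sign.ACTIVATING),
    "7": RegulatoryEdge("E2F", "Myc", Sign.ACTIVATING),
    "8": RegulatoryEdge("CycE", "Myc", Sign.ACTIVATING),
}


def five_node_variant(labels: tuple[str, ...] = ()) -> RegulatoryNetwork:
    """One of the 12 five-node subnetworks, by its optional-edge labels."""
    if "7" in labels and "8" in labels:
        raise ValueError("at most one of edges 7 and 8")
    base = five_node_best()
    edges = list(base.edges) + [_FIVE_NODE_OPTIONAL[l] for l in labels]
    return network_from_edges(base.nodes, edges)


def five_node_variants() -> dict[str, RegulatoryNetwork]:
    """All 12 screened five-node subnetworks keyed by their edge labels."""
    out = {}
    for back in ((), ("7",), ("8",)):
        for fwd in ((), ("2a",), ("2b",), ("2a", "2b")):
            labels = fwd + back
            key = " ".join(labels) if labels else "neither"
            out[key] = five_node_variant(labels)
    return out


#: 6-node network: the best 5-node network with the kinase inhibitor p27
#: (sequestered by CycD, degraded via CycE, and repressing CycE).
P27_TEXT = """\
Myc :
CycD : (Myc)
Rb : (~CycD)(~CycE)
E2F : (~Rb)
CycE : (E2F)(~p27)
p27 : (~CycD)(~CycE)
"""


def p27_network() -> RegulatoryNetwork:
    return parse_network(P27_TEXT)
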