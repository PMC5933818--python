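"""DOT and JSON emission for factor graphs, STGs, Morse graphs, and reports.

DOT output is plain text (render with any Graphviz installation); JSON
schemas are versioned and round-trip through the report readers in
:mod:`switchdyn.screening`.
"""

from __future__ import annotations

import json

from .network import RegulatoryNetwork
from .factorgraph import FactorGraph, FactorAssignment
from .dynamics import MorseGraph, StateTransitionGraph

SCHEMA_VERSION = 1


def _quote(s: str) -> str:
    return '"' + s.replace('"', r"\"") + '"'


def factor_graph_to_dot(fg: FactorGraph) -> str:
    """Factor-graph vertices as ``id: g/order`` boxes."""
    lines = [f"graph PG_{fg.node} {{", "  node [shape=box];"]
    for i, fn in enumerate(fg.vertices):
        label = f"{i}: g={''.join(map(str, fn.g))} O={'<'.join(fn.order)}"
        lines.append(f"  v{i} [label={_quote(label)}];")
    for i, j in fg.edges():
        lines.append(f"  v{i} -- v{j};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def stg_to_dot(stg: StateTransitionGraph, walls: bool = False) -> str:
    """Domains as boxes; with ``walls=True`` the didactic bipartite form is
    emitted, inserting a circle vertex on every wall between domains."""
    lines = ["digraph STG {", "  node [shape=box];"]
    name = {d: "d" + "_".join(map(str, d)) for d in stg.domains}
    for d in stg.domains:
        lines.append(f"  {name[d]} [label={_quote(str(d))}];")
    wall_count = 0
    for d, outs in stg.succ.items():
        for e in outs:
            if d == e:
                lines.append(f"  {name[d]} -> {name[d]};")
            elif walls:
                w = f"w{wall_count}"
                wall_count += 1
                lines.append(f"  {w} [shape=circle, label=\"\", width=0.15];")
                lines.append(f"  {name[d]} -> {w} -> {name[e]};")
            else:
                lines.append(f"  {name[d]} -> {name[e]};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def morse_graph_to_dot(mg: MorseGraph) -> str:
    """Morse nodes with FP labels; minimal nodes (attractors) double-circled."""
    minimal = set(mg.minimal_nodes())
    lines = ["digraph MorseGraph {"]
    for i, m in enumerate(mg.nodes):
        shape = "doublecircle" if i in minimal else "ellipse"
        lines.append(f"  m{i} [shape={shape}, label={_quote(str(m))}];")
    # emit the transitive reduction of the order for readability
    order = set(mg.order)
    for i, j in sorted(order):
        if any((i, k) in order and (k, j) in order for k in range(len(mg.nodes))):
            continue
        lines.append(f"  m{i} -> m{j};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_dot(obj, **kwargs) -> str:
    """Dispatch DOT emission on the object type."""
    if isinstance(obj, FactorGraph):
        return factor_graph_to_dot(obj)
    if isinstance(obj, StateTransitionGraph):
        return stg_to_dot(obj, **kwargs)
    if isinstance(obj, MorseGraph):
        return morse_graph_to_dot(obj)
    raise TypeError(f"no DOT export for {type(obj).__name__}")


def factor_graph_to_json(fg: FactorGraph) -> str:
    """Vertex ids, g as a flat table over input combinations in binary
    order, O as the rank list of out-edge targets."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "node": fg.node,
        "n_inputs": fg.n_inputs,
        "n_outputs": fg.n_outputs,
        "sources": list(fg.sources),
        "vertices": [
            {"id": i, "g": list(fn.g), "order": list(fn.order)}
            for i, fn in enumerate(fg.vertices)
        ],
        "edges": fg.edges(),
    }
    return json.dumps(payload, indent=1)


def assignment_to_json(net: RegulatoryNetwork, assignment: FactorAssignment) -> str:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "nodes": {
            n: {"g": list(assignment[n].g), "order": list(assignment[n].order)}
            for n in net.nodes
        },
    }
    return json.dumps(payload, indent=1)


def morse_graph_to_json(mg: MorseGraph, parameter_id=None) -> str:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "parameter_id": parameter_id,
        "nodes": [
            {
                "domains": sorted(map(list, m.domains)),
                "fp": list(m.fp_label) if m.is_fp else None,
            }
            for m in mg.nodes
        ],
        "order": sorted(map(list, mg.order)),
        "minimal": mg.minimal_nodes(),
    }
    return json.dumps(payload, indent=1)
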