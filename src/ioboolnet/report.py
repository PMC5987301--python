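"""Serialization: DOT / GraphML exports, JSON reports, scheme files."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Optional, Tuple

import networkx as nx
import yaml

from .core import IOBooleanModule, TransitionGraph, bitstring, parse_module
from .interconnect import InterconnectionScheme


def transition_graph_to_networkx(graph: TransitionGraph) -> nx.DiGraph:
    """The transition graph as a digraph with bit-string vertex labels."""
    g = nx.DiGraph(module=graph.module_name,
                   input_profile="".join(map(str, graph.input_profile)))
    n = graph.n
    for i in range(graph.n_states):
        g.add_node(i, label=bitstring(i, n))
    coo = graph.adjacency.tocoo()
    g.add_edges_from(zip(coo.row.tolist(), coo.col.tolist()))
    return g


def write_dot(graph, path, highlight: Iterable[int] = ()) -> None:
    """Minimal DOT writer (vertex label attribute, optional highlighting)."""
    highlight = set(highlight)
    if isinstance(graph, TransitionGraph):
        graph = transition_graph_to_networkx(graph)
    lines = ["digraph G {"]
    for v, data in graph.nodes(data=True):
        label = data.get("label", str(v))
        attrs = f'label="{label}"'
        if v in highlight:
            attrs += ', style=filled, fillcolor="orange"'
        lines.append(f'  "{v}" [{attrs}];')
    for a, b in graph.edges():
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(graph, path) -> None:
    if isinstance(graph, TransitionGraph):
        graph = transition_graph_to_networkx(graph)
    nx.write_graphml(graph, path)


def write_json(obj, path: Optional[str]) -> str:
    text = json.dumps(obj, indent=2, default=_json_default)
    if path:
        Path(path).write_text(text + "\n")
    return text


def _json_default(obj):
    import numpy as np
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def asymptotic_graph_report(graph, attractors=None) -> dict:
    """JSON-ready description of an asymptotic graph and its terminal SCCs."""
    report = {
        "modules": [m.name for m in graph.scheme.modules],
        "vertex_count": graph.vertex_count,
        "vertices": [graph.vertex_label(v) for v in range(graph.vertex_count)],
        "arcs": sorted([graph.vertex_label(a), graph.vertex_label(b)]
                       for a, b in graph.arcs),
    }
    if attractors is not None:
        report["attractors"] = [{
            "labels": list(a.labels),
            "pi_size": a.pi_size,
            "is_singleton": a.is_singleton,
            "status": a.status,
        } for a in attractors]
    return report


# ---------------------------------------------------------------------------
# scheme files

def load_scheme_file(path) -> InterconnectionScheme:
    """Load an interconnection scheme from a YAML description.

    Format::

        modules:
          A: path/to/module_a.bnetio
          B: path/to/module_b.bnetio
        wiring:
          - A.u1 <- B.out1
          - B.v1 <- A.out1

    Module file paths are resolved relative to the scheme file.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "modules" not in doc or "wiring" not in doc:
        raise ValueError("scheme file needs 'modules' and 'wiring' sections")
    names = list(doc["modules"])
    modules = []
    for name in names:
        mpath = Path(doc["modules"][name])
        if not mpath.is_absolute():
            mpath = path.parent / mpath
        modules.append(parse_module(mpath.read_text(), name_hint=name))
    index = {name: k for k, name in enumerate(names)}
    wiring: Dict[Tuple[int, str], Tuple[int, str]] = {}
    for line in doc["wiring"]:
        try:
            dst, src = [s.strip() for s in line.split("<-")]
            dmod, dinp = dst.split(".")
            smod, sout = src.split(".")
        except ValueError:
            raise ValueError(
                f"wiring line must read 'A.input <- B.output': {line!r}")
        wiring[(index[dmod], dinp)] = (index[smod], sout)
    return InterconnectionScheme(tuple(modules), wiring)
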