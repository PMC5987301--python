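"""The asymptotic graph: attractors of an interconnection from its modules.

Vertices are cross products of the modules' same-output attractor sets (the
output cuts of the terminal SCCs of every per-input transition graph).  An
arc lets exactly one module switch attractor set: the module is re-analyzed
under the input profile read off the other modules' output labels, and the
arc exists iff some state of the current set can reach the target set in
that transition graph.  Terminal SCCs of this graph locate *all* attractors
of the interconnected network (possibly plus rare spurious ones); the map
``pi`` expands a set of vertices back to composite states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .core import Bits, DEFAULT_STATE_CAP
from .graphs import AttractorCut, ModuleAnalysis
from .interconnect import InterconnectionScheme

#: module prefixes used in printed vertex labels
_PREFIXES = "ABCDEFGH"

VertexKey = Tuple[int, ...]   # one 1-based flat cut index per module


@dataclass
class AsymptoticGraph:
    """The asymptotic graph of an interconnection."""

    scheme: InterconnectionScheme
    analyses: List[ModuleAnalysis]
    vertices: List[VertexKey]
    vertex_ids: Dict[VertexKey, int]
    arcs: Set[Tuple[int, int]]          # vertex-id pairs, self-arcs excluded
    self_arcs: Set[int]                  # vertices with a recorded self-arc
    #: per vertex, per module: (input profile used, reachable target flat ids)
    moves: List[List[Tuple[Bits, List[int]]]]

    @property
    def vertex_count(self) -> int:
        return len(self.vertices)

    def cut(self, k: int, flat_index: int) -> AttractorCut:
        return self.analyses[k].cut_by_flat(flat_index)

    def vertex_label(self, vid: int) -> str:
        parts = [self.cut(k, f).label(_PREFIXES[k])
                 for k, f in enumerate(self.vertices[vid])]
        return "x".join(parts)

    def digraph(self) -> nx.DiGraph:
        """The arc structure as a networkx digraph (self-arcs omitted)."""
        g = nx.DiGraph()
        g.add_nodes_from(range(self.vertex_count))
        g.add_edges_from(self.arcs)
        return g

    def pi(self, vids: Sequence[int]) -> np.ndarray:
        """Composite states covered by a set of vertices (sorted, deduped)."""
        return pi_states(self, vids)


def build_asymptotic_graph(scheme: InterconnectionScheme,
                           cap: int = DEFAULT_STATE_CAP,
                           analyses: Optional[List[ModuleAnalysis]] = None
                           ) -> AsymptoticGraph:
    """Construct the asymptotic graph of an interconnection."""
    if analyses is None:
        analyses = [ModuleAnalysis(m, cap=cap) for m in scheme.modules]
    K = len(scheme.modules)
    vertices = [tuple(c.flat_index for c in combo)
                for combo in product(*(a.cuts for a in analyses))]
    vertex_ids = {v: i for i, v in enumerate(vertices)}
    arcs: Set[Tuple[int, int]] = set()
    self_arcs: Set[int] = set()
    moves: List[List[Tuple[Bits, List[int]]]] = []
    for vid, vtx in enumerate(vertices):
        cuts = [analyses[k].cut_by_flat(f) for k, f in enumerate(vtx)]
        alphas = {k: c.alpha for k, c in enumerate(cuts)}
        vertex_moves: List[Tuple[Bits, List[int]]] = []
        for k in range(K):
            u = scheme.input_profile_of(k, alphas)
            closure = analyses[k].closure(u, cuts[k])
            reachable: List[int] = []
            for target in analyses[k].cuts_by_input[u]:
                if closure[target.states].any():
                    reachable.append(target.flat_index)
                    dst = list(vtx)
                    dst[k] = target.flat_index
                    did = vertex_ids[tuple(dst)]
                    if did == vid:
                        self_arcs.add(vid)
                    else:
                        arcs.add((vid, did))
            vertex_moves.append((u, reachable))
        moves.append(vertex_moves)
    return AsymptoticGraph(scheme, analyses, vertices, vertex_ids,
                           arcs, self_arcs, moves)


def pi_states(graph: AsymptoticGraph, vids: Sequence[int]) -> np.ndarray:
    """Expand vertices to composite state indices (union, deduplicated).

    Attractor sets of one module under different inputs may overlap as
    state sets, so the union must deduplicate.
    """
    dims = [m.n for m in graph.scheme.modules]
    chunks = []
    for vid in vids:
        parts = [graph.cut(k, f).states
                 for k, f in enumerate(graph.vertices[vid])]
        idx = parts[0].astype(np.int64)
        for states, n in zip(parts[1:], dims[1:]):
            idx = (idx[:, None] << n) | states[None, :].astype(np.int64)
            idx = idx.ravel()
        chunks.append(idx)
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(chunks))


@dataclass
class AsymptoticAttractor:
    """A terminal SCC of the asymptotic graph with its state expansion."""

    vertex_ids: Tuple[int, ...]
    labels: Tuple[str, ...]
    pi: np.ndarray
    is_singleton: bool
    #: 'true', 'spurious' or 'undecided'; singletons are always 'true'
    status: str = "undecided"
    matched_attractor: Optional[int] = None

    @property
    def pi_size(self) -> int:
        return len(self.pi)


def asymptotic_attractors(graph: AsymptoticGraph) -> List[AsymptoticAttractor]:
    """Terminal SCCs of the asymptotic graph (self-arcs ignored)."""
    g = graph.digraph()
    comps = list(nx.strongly_connected_components(g))
    out: List[AsymptoticAttractor] = []
    for comp in comps:
        if any(dst not in comp for src, dst in graph.arcs if src in comp):
            continue
        vids = tuple(sorted(comp))
        attr = AsymptoticAttractor(
            vertex_ids=vids,
            labels=tuple(graph.vertex_label(v) for v in vids),
            pi=pi_states(graph, vids),
            is_singleton=len(vids) == 1,
        )
        if attr.is_singleton:
            attr.status = "true"   # singletons are never spurious
        out.append(attr)
    out.sort(key=lambda a: a.vertex_ids[0])
    return out


def classify_spurious(attractor: AsymptoticAttractor,
                      oracle_attractors: Optional[Sequence[np.ndarray]]
                      ) -> AsymptoticAttractor:
    """Match a terminal SCC against true attractors of an oracle.

    The oracle is the attractor list of the full transition graph or of the
    cross graph, as composite state sets.  ``pi(R)`` contained in some true
    attractor marks a match; otherwise the SCC is spurious.  A singleton
    terminal SCC is certified non-spurious without consulting any oracle.
    """
    if oracle_attractors is not None:
        matched = None
        for qi, q in enumerate(oracle_attractors):
            if np.isin(attractor.pi, q, assume_unique=True).all():
                matched = qi
                break
        attractor.matched_attractor = matched
        attractor.status = "true" if matched is not None else "spurious"
        if attractor.is_singleton and attractor.status == "spurious":
            raise AssertionError(
                "a singleton terminal SCC can never be spurious; "
                "oracle and asymptotic graph disagree")
    elif attractor.is_singleton:
        attractor.status = "true"
    else:
        attractor.status = "undecided"
    return attractor


def accuracy(attractor: AsymptoticAttractor,
             true_attractor: np.ndarray) -> float:
    """Fraction |pi(R)| / |Q| of the true attractor recovered, in (0, 1]."""
    if attractor.status == "spurious":
        raise ValueError("accuracy is undefined for a spurious attractor")
    q = len(true_attractor)
    if q == 0:
        raise ValueError("true attractor must be non-empty")
    return len(attractor.pi) / q
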