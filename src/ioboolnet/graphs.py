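"""SCC decomposition, attractors, output cuts, reachability and basins.

Attractors of an asynchronous Boolean network are the terminal strongly
connected components (zero out-degree in the condensation) of its state
transition graph; singleton attractors are exactly the fixed points.  Each
attractor is further *cut* by the module's output function into same-output
attractor sets, the building blocks of the asymptotic graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph

from .core import (IOBooleanModule, TransitionGraph, Bits, DEFAULT_STATE_CAP,
                   bitstring, build_transition_graph, input_profiles,
                   output_ints, profile_int)


@dataclass(frozen=True)
class SCCDecomposition:
    """Strongly connected components of a digraph over 0..N-1.

    Components are relabelled deterministically by ascending minimal member,
    so ``components[0]`` always contains the smallest vertex index.
    """

    labels: np.ndarray                 # vertex -> component id
    components: Tuple[np.ndarray, ...]  # sorted member arrays
    terminal_flags: np.ndarray         # per component, True iff no arc leaves
    condensation_arcs: frozenset       # deduplicated (ci, cj) pairs, ci != cj

    @property
    def n_components(self) -> int:
        return len(self.components)

    def terminal_components(self) -> List[np.ndarray]:
        return [c for c, t in zip(self.components, self.terminal_flags) if t]


def scc_decompose(adjacency: sp.spmatrix) -> SCCDecomposition:
    """Linear-time SCC decomposition with terminal flags and condensation."""
    adjacency = adjacency.tocsr()
    n = adjacency.shape[0]
    if n < 1:
        raise ValueError("digraph needs at least one vertex")
    n_comp, raw = csgraph.connected_components(
        adjacency, directed=True, connection="strong")
    # relabel by ascending minimal vertex for deterministic reports
    first_seen = np.full(n_comp, n, dtype=np.int64)
    np.minimum.at(first_seen, raw, np.arange(n))
    order = np.argsort(first_seen, kind="stable")
    remap = np.empty(n_comp, dtype=np.int64)
    remap[order] = np.arange(n_comp)
    labels = remap[raw]

    comp_members: List[List[int]] = [[] for _ in range(n_comp)]
    for v, c in enumerate(labels):
        comp_members[c].append(v)
    components = tuple(np.asarray(m, dtype=np.int64) for m in comp_members)

    coo = adjacency.tocoo()
    src_c = labels[coo.row]
    dst_c = labels[coo.col]
    cross = src_c != dst_c
    arcs = frozenset(zip(src_c[cross].tolist(), dst_c[cross].tolist()))
    terminal = np.ones(n_comp, dtype=bool)
    for ci, _ in arcs:
        terminal[ci] = False
    return SCCDecomposition(labels, components, terminal, arcs)


def attractors(module: IOBooleanModule, u: Sequence[int],
               cap: int = DEFAULT_STATE_CAP) -> List[np.ndarray]:
    """Terminal SCCs (attractors) of the transition graph under input ``u``.

    Returned as sorted 0-based state index arrays, in ascending
    minimal-state order.
    """
    graph = build_transition_graph(module, u, cap=cap)
    return attractors_of_graph(graph)


def attractors_of_graph(graph: TransitionGraph) -> List[np.ndarray]:
    dec = scc_decompose(graph.adjacency)
    terms = dec.terminal_components()
    return sorted(terms, key=lambda a: int(a[0]))


def output_cut(attractor: np.ndarray, module: IOBooleanModule
               ) -> List[Tuple[Bits, np.ndarray]]:
    """Split an attractor by output profile, ascending output value.

    Returns ``[(alpha, states), ...]`` with empty slices omitted; the state
    arrays partition the attractor.
    """
    attractor = np.asarray(attractor, dtype=np.int64)
    if attractor.size == 0:
        raise ValueError("attractor must be non-empty")
    outs = output_ints(module)[attractor]
    cuts = []
    for val in np.unique(outs):
        states = attractor[outs == val]
        alpha = tuple(int(b) for b in format(int(val), f"0{module.q}b")) \
            if module.q else ()
        cuts.append((alpha, states))
    return cuts


# ---------------------------------------------------------------------------
# reachability

def reachable_from_set(adjacency: sp.spmatrix,
                       sources: Sequence[int]) -> np.ndarray:
    """Forward closure of ``sources``: all vertices reachable (incl. sources)."""
    adjacency = adjacency.tocsr()
    n = adjacency.shape[0]
    reached = np.zeros(n, dtype=bool)
    frontier = np.unique(np.asarray(list(sources), dtype=np.int64))
    if frontier.size == 0:
        return np.empty(0, dtype=np.int64)
    reached[frontier] = True
    while frontier.size:
        nxt = np.unique(adjacency[frontier].indices)
        nxt = nxt[~reached[nxt]]
        reached[nxt] = True
        frontier = nxt
    return np.nonzero(reached)[0]


def weak_basin(module: IOBooleanModule, u: Sequence[int],
               target: Sequence[int],
               cap: int = DEFAULT_STATE_CAP) -> np.ndarray:
    """States from which some trajectory reaches ``target`` under input ``u``.

    This is the backward closure of the target set (the *weak* basin: under
    asynchronous dynamics a state may also reach other attractors).
    """
    target = np.asarray(list(target), dtype=np.int64)
    if target.size == 0:
        raise ValueError("target must be non-empty")
    graph = build_transition_graph(module, u, cap=cap)
    return reachable_from_set(graph.adjacency.T.tocsr(), target)


# ---------------------------------------------------------------------------
# whole-module analysis (all input profiles), the substrate of the
# asymptotic-graph and probabilistic layers

@dataclass(frozen=True)
class AttractorCut:
    """A same-output slice of one terminal SCC (one ``A_[i]``).

    ``flat_index`` is the 1-based running index over all cuts of the module,
    input profiles in ascending order, then attractors by ascending minimal
    state, then cuts by ascending output value -- the enumeration used in
    printed labels like ``A112``.
    """

    module_name: str
    input_profile: Bits
    alpha: Bits
    attractor_index: int        # 1-based, per input profile
    flat_index: int             # 1-based, over the whole module
    states: np.ndarray          # sorted 0-based state indices
    parent_states: np.ndarray   # the full terminal SCC this was cut from

    def label(self, prefix: str = "A") -> str:
        """Label in the style ``A112`` (decimal 1 = logical 0)."""
        u_hat = "".join(str(b + 1) for b in self.input_profile)
        a_hat = "".join(str(b + 1) for b in self.alpha)
        return f"{prefix}{u_hat}{a_hat}{self.flat_index}"

    @property
    def is_fixed_point(self) -> bool:
        return len(self.parent_states) == 1


class ModuleAnalysis:
    """Per-input transition graphs, attractors and output cuts of a module.

    Forward closures used by the asymptotic-graph construction are memoized
    per (input profile, source set).
    """

    def __init__(self, module: IOBooleanModule, cap: int = DEFAULT_STATE_CAP):
        self.module = module
        self.cap = cap
        self.graphs: Dict[Bits, TransitionGraph] = {}
        self.attractors_by_input: Dict[Bits, List[np.ndarray]] = {}
        self.cuts_by_input: Dict[Bits, List[AttractorCut]] = {}
        self.cuts: List[AttractorCut] = []
        flat = 0
        for u in input_profiles(module.p):
            g = build_transition_graph(module, u, cap=cap)
            self.graphs[u] = g
            attrs = attractors_of_graph(g)
            self.attractors_by_input[u] = attrs
            cuts_u: List[AttractorCut] = []
            for ai, attr in enumerate(attrs, start=1):
                for alpha, states in output_cut(attr, module):
                    flat += 1
                    cuts_u.append(AttractorCut(
                        module_name=module.name, input_profile=u,
                        alpha=alpha, attractor_index=ai, flat_index=flat,
                        states=states, parent_states=attr))
            self.cuts_by_input[u] = cuts_u
            self.cuts.extend(cuts_u)
        self._closure_memo: Dict[Tuple[Bits, int], np.ndarray] = {}

    @property
    def L(self) -> int:
        """Total number of same-output attractor sets."""
        return len(self.cuts)

    def cut_by_flat(self, flat_index: int) -> AttractorCut:
        return self.cuts[flat_index - 1]

    def closure(self, u: Bits, cut: AttractorCut) -> np.ndarray:
        """Forward closure of ``cut.states`` in the graph under input ``u``.

        Returned as a boolean mask over the state space (memoized).
        """
        key = (u, cut.flat_index)
        mask = self._closure_memo.get(key)
        if mask is None:
            reach = reachable_from_set(self.graphs[u].adjacency, cut.states)
            mask = np.zeros(2 ** self.module.n, dtype=bool)
            mask[reach] = True
            self._closure_memo[key] = mask
        return mask

    def scc_partition(self, u: Bits) -> np.ndarray:
        """Component label per state for the graph under input ``u``."""
        return scc_decompose(self.graphs[u].adjacency).labels


def attractor_report(module: IOBooleanModule,
                     cap: int = DEFAULT_STATE_CAP) -> dict:
    """JSON-ready attractor report: per input profile, attractors and cuts."""
    analysis = ModuleAnalysis(module, cap=cap)
    report = {"module": module.name, "n": module.n, "p": module.p,
              "q": module.q, "inputs": []}
    for u in input_profiles(module.p):
        entry = {"input_profile": "".join(map(str, u)), "attractors": []}
        for attr in analysis.attractors_by_input[u]:
            cuts = [c for c in analysis.cuts_by_input[u]
                    if c.parent_states is attr or
                    np.array_equal(c.parent_states, attr)]
            entry["attractors"].append({
                "size": int(len(attr)),
                "is_fixed_point": len(attr) == 1,
                "states": [bitstring(int(s), module.n) for s in attr]
                if len(attr) <= 64 else None,
                "output_cuts": [
                    {"label": c.label(module.name[:1].upper() or "A"),
                     "alpha": "".join(map(str, c.alpha)),
                     "size": int(len(c.states))} for c in cuts],
            })
        report["inputs"].append(entry)
    return report
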