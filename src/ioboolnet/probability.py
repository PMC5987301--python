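"""Probabilistic layer: edge probabilities and relative attractor weights.

Each module's same-output attractor sets receive *incidence probabilities*
(uniform, basin-proportional, or user supplied).  Asymptotic-graph arcs are
then weighted: a vertex first chooses which module updates (probability
``rho_A`` for the first module, adjusted to 0 or 1 when only one side can
actually move) and then switches to a reachable attractor set with
probability proportional to its incidence weight.  Condensing the weighted
graph over its SCCs yields an absorbing Markov chain in canonical form
``[[Q, R], [0, I]]``; the fundamental-matrix solve ``(I - Q)^-1 R`` gives
the absorption probabilities, and each absorbing component's *relative
probability* combines its own incidence mass with the absorbed mass of
every transient component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .asymptotic import AsymptoticGraph
from .graphs import ModuleAnalysis, reachable_from_set

WeightSpec = Union[str, np.ndarray, Sequence[float]]

#: switch to a sparse linear solve above this many transient components
DENSE_SOLVE_LIMIT = 2000


def incidence_weights(analysis: ModuleAnalysis,
                      source: WeightSpec = "uniform") -> np.ndarray:
    """Incidence probabilities of a module's same-output attractor sets.

    Modes:

    * ``"uniform"`` -- 1/L each;
    * ``"uniform_per_input"`` -- uniform over the sets of each input
      profile, then averaged over the 2**p input profiles;
    * ``"basin"`` -- proportional to the weak-basin size of each set in its
      own input graph, normalized over all sets of the module;
    * ``"basin_per_input"`` -- basin sizes normalized within each input
      profile, then averaged over the 2**p input profiles;
    * an explicit array of length L (validated to be non-negative and to
      sum to 1 within 1e-9).
    """
    L = analysis.L
    if isinstance(source, str):
        if source == "uniform":
            return np.full(L, 1.0 / L)
        if source == "uniform_per_input":
            w = np.empty(L)
            profiles = {c.input_profile for c in analysis.cuts}
            for u in profiles:
                idx = [c.flat_index - 1 for c in analysis.cuts
                       if c.input_profile == u]
                w[idx] = 1.0 / len(idx) / len(profiles)
            return w
        if source in ("basin", "basin_per_input"):
            sizes = np.empty(L)
            for c in analysis.cuts:
                adj_t = analysis.graphs[c.input_profile].adjacency.T.tocsr()
                sizes[c.flat_index - 1] = len(
                    reachable_from_set(adj_t, c.states))
            if source == "basin":
                return sizes / sizes.sum()
            w = np.empty(L)
            profiles = {c.input_profile for c in analysis.cuts}
            for u in profiles:
                idx = [c.flat_index - 1 for c in analysis.cuts
                       if c.input_profile == u]
                w[idx] = sizes[idx] / sizes[idx].sum() / len(profiles)
            return w
        raise ValueError(f"unknown weight source {source!r}")
    w = np.asarray(source, dtype=float)
    if w.shape != (L,):
        raise ValueError(f"expected {L} weights, got shape {w.shape}")
    if (w < 0).any():
        raise ValueError("incidence weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"incidence weights sum to {w.sum()}, not 1")
    return w


@dataclass
class ProbabilisticAsymptoticGraph:
    """An asymptotic graph with row-stochastic edge probabilities."""

    graph: AsymptoticGraph
    rho_A: float
    weights: Tuple[np.ndarray, np.ndarray]
    #: (src vid, dst vid) -> probability; includes self-loops
    edge_probs: Dict[Tuple[int, int], float]
    #: effective update probability per vertex (None for absorbing vertices)
    effective_rho: List[Optional[float]]

    def row_sums(self) -> np.ndarray:
        sums = np.zeros(self.graph.vertex_count)
        for (src, _), p in self.edge_probs.items():
            sums[src] += p
        return sums

    def vertex_incidence(self, vid: int) -> float:
        """Joint incidence probability of a vertex, w_A^i * w_B^j."""
        i, j = self.graph.vertices[vid]
        return float(self.weights[0][i - 1] * self.weights[1][j - 1])


def effective_rho(has_a_switch: bool, has_b_switch: bool,
                  rho_A: float) -> Optional[float]:
    """Effective first-module update probability of one vertex.

    0 when every outgoing arc keeps the first module's attractor set fixed,
    1 when every outgoing arc keeps the second module's set fixed, ``rho_A``
    when both kinds occur, and None when there is no outgoing arc at all
    (the vertex is absorbing).
    """
    if not has_a_switch and not has_b_switch:
        return None
    if not has_a_switch:
        return 0.0
    if not has_b_switch:
        return 1.0
    return rho_A


def switch_probabilities(weights: np.ndarray,
                         reachable_flat: Sequence[int]) -> Dict[int, float]:
    """Conditional switch probabilities over the reachable attractor sets.

    Incidence weights restricted to the reachable sets ``J`` and
    renormalized; sets outside ``J`` get probability 0 (omitted).
    """
    if not reachable_flat:
        raise ValueError("every state reaches at least one attractor; "
                         "empty reachable set is impossible")
    denom = sum(weights[k - 1] for k in reachable_flat)
    return {k: float(weights[k - 1] / denom) for k in reachable_flat}


def edge_probabilities(graph: AsymptoticGraph, rho_A: float = 0.5,
                       weights_a: WeightSpec = "uniform",
                       weights_b: WeightSpec = "uniform"
                       ) -> ProbabilisticAsymptoticGraph:
    """Attach probabilities to asymptotic-graph arcs (two-module schemes)."""
    if len(graph.scheme.modules) != 2:
        raise ValueError("the probabilistic layer handles two-module schemes")
    if not 0.0 <= rho_A <= 1.0:
        raise ValueError("rho_A must lie in [0, 1]")
    wa = incidence_weights(graph.analyses[0], weights_a)
    wb = incidence_weights(graph.analyses[1], weights_b)
    edge_probs: Dict[Tuple[int, int], float] = {}
    eff: List[Optional[float]] = []
    for vid, (i, j) in enumerate(graph.vertices):
        (ua, ja), (ub, jb) = graph.moves[vid]
        has_a = any(k != i for k in ja)
        has_b = any(k != j for k in jb)
        rho_bar = effective_rho(has_a, has_b, rho_A)
        eff.append(rho_bar)
        if rho_bar is None:
            edge_probs[(vid, vid)] = 1.0   # absorbing vertex: self-loop 1
            continue
        if rho_bar > 0.0:
            for k, s in switch_probabilities(wa, ja).items():
                dst = graph.vertex_ids[(k, j)]
                p = rho_bar * s
                if p > 0.0:
                    edge_probs[(vid, dst)] = edge_probs.get((vid, dst), 0.0) + p
        if rho_bar < 1.0:
            for k, s in switch_probabilities(wb, jb).items():
                dst = graph.vertex_ids[(i, k)]
                p = (1.0 - rho_bar) * s
                if p > 0.0:
                    edge_probs[(vid, dst)] = edge_probs.get((vid, dst), 0.0) + p
    return ProbabilisticAsymptoticGraph(graph, rho_A, (wa, wb),
                                        edge_probs, eff)


@dataclass
class CondensedChain:
    """Absorbing Markov chain over the SCCs of the asymptotic graph."""

    pgraph: ProbabilisticAsymptoticGraph
    components: List[Tuple[int, ...]]   # vertex ids, canonical order
    absorbing: np.ndarray               # flag per component
    M: np.ndarray                       # m x m row-stochastic, canonical form
    P_C: np.ndarray                     # incidence probability per component
    M_absorp: np.ndarray                # (m-r) x r absorption probabilities

    @property
    def m(self) -> int:
        return len(self.components)

    @property
    def r(self) -> int:
        return int(self.absorbing.sum())

    def component_labels(self, ci: int) -> Tuple[str, ...]:
        g = self.pgraph.graph
        return tuple(g.vertex_label(v) for v in self.components[ci])


def condense_chain(pgraph: ProbabilisticAsymptoticGraph) -> CondensedChain:
    """Contract the weighted asymptotic graph to an absorbing Markov chain.

    Inter-component edge probabilities are summed and each transient row is
    renormalized to 1 (intra-component mass is discarded); absorbing rows
    are unit vectors.  Components are ordered transient-first (canonical
    form ``[[Q, R], [0, I]]``).
    """
    graph = pgraph.graph
    g = graph.digraph()
    comps = [tuple(sorted(c)) for c in nx.strongly_connected_components(g)]
    comps.sort(key=lambda c: c[0])
    comp_of = {}
    for ci, comp in enumerate(comps):
        for v in comp:
            comp_of[v] = ci
    m = len(comps)
    absorbing = np.ones(m, dtype=bool)
    for src, dst in graph.arcs:
        if comp_of[src] != comp_of[dst]:
            absorbing[comp_of[src]] = False
    if not absorbing.any():
        raise AssertionError("a finite condensation always has an "
                             "absorbing component")
    order = ([ci for ci in range(m) if not absorbing[ci]] +
             [ci for ci in range(m) if absorbing[ci]])
    rank = {ci: k for k, ci in enumerate(order)}

    M = np.zeros((m, m))
    for (src, dst), p in pgraph.edge_probs.items():
        ci, cj = comp_of[src], comp_of[dst]
        if ci != cj:
            M[rank[ci], rank[cj]] += p
    r = int(absorbing.sum())
    t = m - r
    for row in range(t):
        total = M[row].sum()
        if total <= 0.0:
            raise AssertionError(
                "transient component with zero outgoing probability; "
                "use an updating probability strictly inside (0, 1)")
        M[row] /= total
    M[t:, :] = 0.0
    M[np.arange(t, m), np.arange(t, m)] = 1.0

    components = [comps[ci] for ci in order]
    P_C = np.zeros(m)
    for k, comp in enumerate(components):
        P_C[k] = sum(pgraph.vertex_incidence(v) for v in comp)

    Q = M[:t, :t]
    R = M[:t, t:]
    if t == 0:
        M_absorp = np.zeros((0, r))
    elif t <= DENSE_SOLVE_LIMIT:
        M_absorp = np.linalg.solve(np.eye(t) - Q, R)
    else:
        M_absorp = spla.spsolve(sp.eye(t, format="csc") - sp.csc_matrix(Q),
                                sp.csc_matrix(R)).toarray()
    return CondensedChain(pgraph, components,
                          np.array([False] * t + [True] * r), M, P_C,
                          M_absorp)


def relative_probabilities(chain: CondensedChain) -> np.ndarray:
    """Relative probability of each absorbing component.

    ``P_rel(C_a^k) = P(C_a^k) + sum_i M_absorp(i, k) P(C_i)`` over the
    transient components ``C_i``; the values sum to 1.
    """
    t = chain.m - chain.r
    p_abs = chain.P_C[t:].copy()
    if t:
        p_abs += chain.M_absorp.T @ chain.P_C[:t]
    total = p_abs.sum()
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(
            f"relative probabilities sum to {total}, expected 1")
    return p_abs


def attractor_probabilities(graph: AsymptoticGraph, rho_A: float = 0.5,
                            weights_a: WeightSpec = "uniform",
                            weights_b: WeightSpec = "uniform"
                            ) -> Dict[str, float]:
    """Convenience wrapper: P_rel keyed by absorbing-component label."""
    pg = edge_probabilities(graph, rho_A, weights_a, weights_b)
    chain = condense_chain(pg)
    p_rel = relative_probabilities(chain)
    t = chain.m - chain.r
    out = {}
    for k in range(chain.r):
        label = "+".join(chain.component_labels(t + k))
        out[label] = float(p_rel[k])
    return out
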