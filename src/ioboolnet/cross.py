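"""The cross graph: exact SCC structure of an interconnection from blocks.

Per module, the strongly connected components of each per-input transition
graph define one partition of the module's state space per input profile.
The *meet* of these partitions (greatest lower bound in the partition
lattice, i.e. the coarsest partition finer than all of them) is computed by
labelling each state with its tuple of per-input component ids and grouping
identical tuples; the blocks are then further cut by output value.  The
cross graph is the Kronecker composition of the per-input transition graphs
*projected onto these blocks*.  Its SCC decomposition is in bijection with
that of the full interconnected graph, and its terminal SCCs expand to
exactly the attractors of the interconnection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .core import Bits, DEFAULT_STATE_CAP, IOBooleanModule, input_profiles
from .graphs import ModuleAnalysis, SCCDecomposition, scc_decompose
from .interconnect import InterconnectionScheme, kron_compose


@dataclass(frozen=True)
class MeetPartition:
    """Output-refined meet of the per-input SCC partitions of one module.

    ``labels`` maps each state to its refined block id; blocks are ordered
    by ascending minimal state.  ``block_alpha`` holds the (constant)
    output profile of each block.
    """

    labels: np.ndarray
    blocks: Tuple[np.ndarray, ...]
    block_alpha: Tuple[Bits, ...]
    n_coarse: int      # block count before the output refinement

    @property
    def M(self) -> int:
        return len(self.blocks)


def partition_meet(partitions: Sequence[np.ndarray]) -> np.ndarray:
    """Meet (coarsest common refinement) of partitions given as label arrays.

    Two states share a block iff they share a component in every input
    partition; blocks are numbered by ascending minimal state.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    size = len(partitions[0])
    for p in partitions:
        if len(p) != size:
            raise ValueError("partitions cover different state spaces")
    stacked = np.stack([np.asarray(p) for p in partitions], axis=1)
    _, inverse = np.unique(stacked, axis=0, return_inverse=True)
    return _relabel_by_min_state(inverse)


def _relabel_by_min_state(labels: np.ndarray) -> np.ndarray:
    n_blocks = int(labels.max()) + 1
    first = np.full(n_blocks, len(labels), dtype=np.int64)
    np.minimum.at(first, labels, np.arange(len(labels)))
    order = np.argsort(first, kind="stable")
    remap = np.empty(n_blocks, dtype=np.int64)
    remap[order] = np.arange(n_blocks)
    return remap[labels]


def refine_by_output(labels: np.ndarray,
                     module: IOBooleanModule) -> MeetPartition:
    """Cut each block by output value (empty slices omitted)."""
    from .core import output_ints
    outs = output_ints(module)
    stacked = np.stack([labels, outs], axis=1)
    _, refined = np.unique(stacked, axis=0, return_inverse=True)
    refined = _relabel_by_min_state(refined)
    n_ref = int(refined.max()) + 1
    blocks = []
    alphas = []
    q = module.q
    for b in range(n_ref):
        members = np.nonzero(refined == b)[0]
        blocks.append(members)
        val = int(outs[members[0]])
        alphas.append(tuple(int(c) for c in format(val, f"0{q}b")) if q
                      else ())
    return MeetPartition(refined, tuple(blocks), tuple(alphas),
                         n_coarse=int(labels.max()) + 1)


def module_meet(analysis: ModuleAnalysis) -> MeetPartition:
    """Meet of a module's per-input SCC partitions, refined by output."""
    partitions = [analysis.scc_partition(u)
                  for u in input_profiles(analysis.module.p)]
    return refine_by_output(partition_meet(partitions), analysis.module)


def project_graph(adjacency: sp.spmatrix, labels: np.ndarray,
                  n_blocks: int) -> sp.csr_matrix:
    """Project a state-level digraph onto partition blocks.

    Block i -> block j (i != j) iff some state-level arc crosses from block
    i to block j; intra-block arcs are dropped (each block lies inside one
    SCC of every per-input graph, so they carry no condensation structure).
    """
    coo = adjacency.tocoo()
    bi = labels[coo.row]
    bj = labels[coo.col]
    keep = bi != bj
    adj = sp.csr_matrix(
        (np.ones(int(keep.sum()), dtype=bool), (bi[keep], bj[keep])),
        shape=(n_blocks, n_blocks))
    adj.sum_duplicates()
    return adj


@dataclass
class CrossGraph:
    """The cross graph of an interconnection."""

    scheme: InterconnectionScheme
    analyses: List[ModuleAnalysis]
    meets: List[MeetPartition]
    projected: List[Dict[Bits, sp.csr_matrix]]   # H^{k,u}, block level
    adjacency: sp.csr_matrix                      # composite, block products
    scc: SCCDecomposition

    @property
    def vertex_count(self) -> int:
        return int(self.adjacency.shape[0])

    def block_tuple(self, vertex: int) -> Tuple[int, ...]:
        """Per-module block indices of a composite vertex (module-major)."""
        out = []
        for meet in reversed(self.meets):
            out.append(vertex % meet.M)
            vertex //= meet.M
        return tuple(reversed(out))

    def expanded_size(self, vertices: Sequence[int]) -> int:
        """Number of composite states covered by a set of cross vertices."""
        total = 0
        for v in vertices:
            size = 1
            for k, b in enumerate(self.block_tuple(v)):
                size *= len(self.meets[k].blocks[b])
            total += size
        return total

    def expand_states(self, vertices: Sequence[int]) -> np.ndarray:
        """Composite state indices covered by cross vertices (sorted).

        Distinct cross vertices expand to disjoint state sets (blocks
        partition each module's state space), so no deduplication is
        needed.
        """
        dims = [m.n for m in self.scheme.modules]
        chunks = []
        for v in vertices:
            parts = [self.meets[k].blocks[b]
                     for k, b in enumerate(self.block_tuple(v))]
            idx = parts[0].astype(np.int64)
            for states, n in zip(parts[1:], dims[1:]):
                idx = (idx[:, None] << n) | states[None, :].astype(np.int64)
                idx = idx.ravel()
            chunks.append(idx)
        return np.sort(np.concatenate(chunks))


def build_cross_graph(scheme: InterconnectionScheme,
                      cap: int = DEFAULT_STATE_CAP,
                      max_vertices: int = 10 ** 7,
                      analyses: Optional[List[ModuleAnalysis]] = None
                      ) -> CrossGraph:
    """Construct the cross graph of an interconnection."""
    if analyses is None:
        analyses = [ModuleAnalysis(m, cap=cap) for m in scheme.modules]
    meets = [module_meet(a) for a in analyses]
    n_vertices = int(np.prod([m.M for m in meets]))
    if n_vertices > max_vertices:
        from .core import ResourceCapError
        raise ResourceCapError(
            f"cross graph would have {n_vertices} vertices "
            f"(> max_vertices={max_vertices})")
    projected = []
    indicators = []
    for a, meet in zip(analyses, meets):
        projected.append({
            u: project_graph(a.graphs[u].adjacency, meet.labels, meet.M)
            for u in input_profiles(a.module.p)})
        inds: Dict[Bits, np.ndarray] = {}
        for alpha in input_profiles(a.module.q):
            inds[alpha] = np.array(
                [ba == alpha for ba in meet.block_alpha], dtype=bool)
        indicators.append(inds)
    adjacency = kron_compose(scheme, projected, indicators)
    scc = scc_decompose(adjacency)
    return CrossGraph(scheme, analyses, meets, projected, adjacency, scc)


@dataclass
class CrossAttractor:
    """A terminal SCC of the cross graph expanded back to states."""

    vertex_ids: Tuple[int, ...]
    size: int
    states: Optional[np.ndarray]    # materialized only below the limit


def cross_attractors(cross: CrossGraph,
                     expand_limit: Optional[int] = 10 ** 6
                     ) -> List[CrossAttractor]:
    """Attractors of the interconnection, from the cross graph.

    Terminal SCCs are expanded back to composite state sets; these are
    exactly the attractors of the interconnected network.  Expansion to
    explicit state arrays is skipped for attractors larger than
    ``expand_limit`` states (pass ``None`` to always materialize).
    """
    out: List[CrossAttractor] = []
    for comp, terminal in zip(cross.scc.components, cross.scc.terminal_flags):
        if not terminal:
            continue
        vids = tuple(int(v) for v in comp)
        size = cross.expanded_size(vids)
        states = None
        if expand_limit is None or size <= expand_limit:
            states = cross.expand_states(vids)
        out.append(CrossAttractor(vids, size, states))
    out.sort(key=lambda a: a.vertex_ids[0])
    return out


def scc_state_labels(cross: CrossGraph) -> np.ndarray:
    """SCC label per composite *state* (for bijection checks; small n only)."""
    dims = [m.n for m in cross.scheme.modules]
    n_total = sum(dims)
    if n_total > 26:
        from .core import ResourceCapError
        raise ResourceCapError("state-level expansion limited to n <= 26")
    labels = np.empty(2 ** n_total, dtype=np.int64)
    for v in range(cross.vertex_count):
        states = cross.expand_states([v])
        labels[states] = cross.scc.labels[v]
    return labels
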