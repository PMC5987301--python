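"""Partition meets, projections and the cross graph (exact recovery)."""

import numpy as np
import pytest
import scipy.sparse as sp

from ioboolnet.core import build_transition_graph, parse_module
from ioboolnet.cross import (build_cross_graph, cross_attractors,
                             module_meet, partition_meet, project_graph,
                             refine_by_output, scc_state_labels)
from ioboolnet.fixtures import load_fixture, scheme
from ioboolnet.graphs import ModuleAnalysis, scc_decompose
from ioboolnet.interconnect import build_full_graph
from ioboolnet.random_nets import random_two_module_scheme


def _partition_sets(labels):
    return {frozenset(np.nonzero(labels == b)[0].tolist())
            for b in np.unique(labels)}


def test_meet_is_idempotent(rng):
    labels = rng.integers(0, 4, size=12)
    met = partition_meet([labels, labels])
    assert _partition_sets(met) == _partition_sets(labels)


def test_meet_is_coarsest_common_refinement(rng):
    """Two elements share a meet block iff they share a block in every
    input partition -- checked exhaustively on random partitions."""
    for _ in range(20):
        parts = [rng.integers(0, 3, size=8) for _ in range(3)]
        met = partition_meet(parts)
        for i in range(8):
            for j in range(8):
                together = all(p[i] == p[j] for p in parts)
                assert (met[i] == met[j]) == together


def test_meet_rejects_mismatched_state_spaces():
    with pytest.raises(ValueError):
        partition_meet([np.zeros(4, dtype=int), np.zeros(8, dtype=int)])


def test_example4_module_partitions():
    a = ModuleAnalysis(load_fixture("example4_A"))
    meet_a = module_meet(a)
    assert _partition_sets(meet_a.labels) == {
        frozenset({0, 2}), frozenset({1, 3})}     # {{*0}, {*1}}
    b = ModuleAnalysis(load_fixture("example4_B"))
    meet_b = module_meet(b)
    assert meet_b.M == 4                           # all singletons
    assert all(len(blk) == 1 for blk in meet_b.blocks)


def test_refine_by_output_conserves_partition(rng):
    m = load_fixture("clock7")
    analysis = ModuleAnalysis(m)
    meet = module_meet(analysis)
    assert sum(len(b) for b in meet.blocks) == 2 ** m.n
    # blocks are output-constant
    from ioboolnet.core import output_ints
    outs = output_ints(m)
    for blk in meet.blocks:
        assert len(np.unique(outs[blk])) == 1


def test_constant_output_block_is_not_split():
    m = parse_module("module c\nx1* = x1\nx2* = x2\noutput y = 1\n")
    labels = np.zeros(4, dtype=np.int64)   # one block, constant output
    refined = refine_by_output(labels, m)
    assert refined.M == 1


def test_projection_onto_singletons_is_identity(rng):
    m = load_fixture("example4_B")
    g = build_transition_graph(m, (0,))
    labels = np.arange(4)
    h = project_graph(g.adjacency, labels, 4)
    assert (h != g.adjacency).nnz == 0


def test_projection_preserves_reachability(rng):
    """Block-level reachability equals the quotient of state-level
    reachability for partitions finer than the SCC partition."""
    from conftest import transitive_closure
    from ioboolnet.random_nets import random_module
    for _ in range(10):
        m = random_module(4, 0, 0, 2.0, rng)
        g = build_transition_graph(m, ())
        labels = scc_decompose(g.adjacency).labels
        n_blocks = int(labels.max()) + 1
        h = project_graph(g.adjacency, labels, n_blocks)
        state_reach = transitive_closure(g.adjacency.toarray())
        block_reach = transitive_closure(h.toarray())
        for i in range(2 ** 4):
            for j in range(2 ** 4):
                assert state_reach[i, j] == block_reach[
                    labels[i], labels[j]]


def test_example4_cross_graph_bijection_with_full_graph():
    s = scheme("example4")
    cross = build_cross_graph(s)
    assert cross.vertex_count == 8
    full = build_full_graph(s)
    assert full.n_states == 16
    full_dec = scc_decompose(full.adjacency)
    expanded = scc_state_labels(cross)
    assert _partition_sets(expanded) == _partition_sets(full_dec.labels)
    # attractor state sets agree exactly
    ours = {frozenset(a.states.tolist()) for a in cross_attractors(cross)}
    truth = {frozenset(c.tolist()) for c in full_dec.terminal_components()}
    assert ours == truth


def test_cross_graph_scc_bijection_on_random_schemes(rng):
    """SCCs of the cross graph expand to exactly the SCCs of the full
    graph, and terminal SCCs to exactly the attractors (small suite; the
    acceptance suite runs the full-size version)."""
    for _ in range(40):
        s = random_two_module_scheme(
            int(rng.integers(2, 6)), int(rng.integers(2, 6)),
            float(rng.uniform(1, 3)), rng)
        cross = build_cross_graph(s)
        assert cross.vertex_count <= 2 ** s.n_total
        full = build_full_graph(s)
        full_dec = scc_decompose(full.adjacency)
        assert _partition_sets(scc_state_labels(cross)) == \
            _partition_sets(full_dec.labels)
        ours = {frozenset(a.states.tolist()) for a in cross_attractors(cross)}
        truth = {frozenset(c.tolist())
                 for c in full_dec.terminal_components()}
        assert ours == truth


def test_asymptotic_vertices_are_unions_of_cross_blocks():
    """Each output-cut terminal SCC is a union of refined meet blocks."""
    s = scheme("example")
    analyses = [ModuleAnalysis(m) for m in s.modules]
    cross = build_cross_graph(s, analyses=analyses)
    for k, analysis in enumerate(analyses):
        labels = cross.meets[k].labels
        for cut in analysis.cuts:
            for b in np.unique(labels[cut.states]):
                block = cross.meets[k].blocks[b]
                assert np.isin(block, cut.states).all()
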