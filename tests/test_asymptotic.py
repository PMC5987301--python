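"""Asymptotic-graph construction, pi reconstruction and spuriousness."""

import numpy as np
import pytest

from conftest import brute_force_attractors
from ioboolnet.asymptotic import (accuracy, asymptotic_attractors,
                                  build_asymptotic_graph, classify_spurious,
                                  pi_states)
from ioboolnet.fixtures import scheme
from ioboolnet.graphs import scc_decompose
from ioboolnet.interconnect import build_full_graph, two_module_scheme
from ioboolnet.random_nets import random_module, random_two_module_scheme


@pytest.fixture(scope="module")
def example3():
    return build_asymptotic_graph(scheme("example"))


def test_example3_vertices_and_cycle(example3):
    g = example3
    assert g.vertex_count == 4
    labeled = {(g.vertex_label(a), g.vertex_label(b)) for a, b in g.arcs}
    # printed cycle (decimal labels: 1 = logical 0, 2 = logical 1)
    assert labeled == {
        ("A111xB121", "A222xB121"),
        ("A222xB121", "A222xB212"),
        ("A222xB212", "A111xB212"),
        ("A111xB212", "A111xB121"),
    }


def test_example3_pi_values(example3):
    g = example3
    by_label = {g.vertex_label(v): v for v in range(g.vertex_count)}
    # pi(A001 x B011) = {001} etc., composite index x-major
    assert pi_states(g, [by_label["A111xB121"]]).tolist() == [1]   # 001
    assert pi_states(g, [by_label["A222xB121"]]).tolist() == [7]   # 111
    assert pi_states(g, [by_label["A222xB212"]]).tolist() == [6]   # 110
    assert pi_states(g, [by_label["A111xB212"]]).tolist() == [0]   # 000
    assert pi_states(g, []).size == 0


def test_example3_terminal_scc_is_contained_in_the_true_attractor(example3):
    attrs = asymptotic_attractors(example3)
    assert len(attrs) == 1
    r = attrs[0]
    assert len(r.vertex_ids) == 4
    full = build_full_graph(scheme("example"))
    q = scc_decompose(full.adjacency).terminal_components()[0]
    assert np.isin(r.pi, q).all()
    assert accuracy(r, q) == pytest.approx(4 / 6)


def test_constant_output_modules_verified_against_full_graph(rng):
    """With constant outputs the inputs never change; every terminal SCC of
    the asymptotic graph must still expand into a true attractor."""
    for _ in range(10):
        a = random_module(3, 1, 1, 2.0, rng, "A", prefix="a_")
        b = random_module(3, 1, 1, 2.0, rng, "B", prefix="b_")
        from ioboolnet.expr import Const
        a = a.__class__(a.name, a.variable_names, a.input_names,
                        a.update_rules, a.output_names, (Const(False),))
        b = b.__class__(b.name, b.variable_names, b.input_names,
                        b.update_rules, b.output_names, (Const(True),))
        s = two_module_scheme(a, b)
        g = build_asymptotic_graph(s)
        dense = build_full_graph(s).adjacency.toarray()
        true_attrs = [np.array(sorted(q))
                      for q in brute_force_attractors(dense)]
        for r in asymptotic_attractors(g):
            classify_spurious(r, true_attrs)
            assert r.status == "true"


def test_singleton_terminal_scc_certified_without_oracle():
    g = build_asymptotic_graph(scheme("yeast_G1"))
    attrs = asymptotic_attractors(g)
    assert len(attrs) == 6
    for a in attrs:
        assert a.is_singleton
        classify_spurious(a, None)
        assert a.status == "true"


def test_nonsingleton_without_oracle_is_undecided():
    g = build_asymptotic_graph(scheme("example"))
    (r,) = asymptotic_attractors(g)
    classify_spurious(r, None)
    assert r.status == "undecided"


def test_accuracy_undefined_for_spurious():
    g = build_asymptotic_graph(scheme("example"))
    (r,) = asymptotic_attractors(g)
    r.status = "spurious"
    with pytest.raises(ValueError):
        accuracy(r, np.arange(6))


def test_vertex_count_bound_on_random_schemes(rng):
    for _ in range(10):
        s = random_two_module_scheme(3, 3, 2.0, rng)
        g = build_asymptotic_graph(s)
        bound = g.analyses[0].L * g.analyses[1].L
        assert g.vertex_count == bound      # all products are non-empty


def test_no_attractor_missed_on_random_schemes(rng):
    """Every attractor of the full graph contains pi(R) of some terminal
    SCC of the asymptotic graph (small random suite; the acceptance suite
    runs the full-size version)."""
    for _ in range(40):
        s = random_two_module_scheme(
            int(rng.integers(2, 6)), int(rng.integers(2, 6)),
            float(rng.uniform(1, 3)), rng)
        g = build_asymptotic_graph(s)
        attrs = asymptotic_attractors(g)
        full = build_full_graph(s)
        dec = scc_decompose(full.adjacency)
        for q in dec.terminal_components():
            q_sorted = np.sort(q)
            assert any(np.isin(r.pi, q_sorted).all() for r in attrs), \
                "attractor missed by the asymptotic graph"
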