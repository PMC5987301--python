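"""Rule composition, output indicators and Kronecker graph composition."""

import numpy as np
import pytest

from ioboolnet.core import (build_transition_graph, parse_module,
                            input_profiles)
from ioboolnet.expr import truth_table_of
from ioboolnet.fixtures import load_fixture, scheme
from ioboolnet.interconnect import (InterconnectionScheme, WiringError,
                                    build_full_graph, compose_rules,
                                    output_indicator, two_module_scheme)
from ioboolnet.random_nets import random_module, random_two_module_scheme

EXAMPLE2_G = [
    [0, 1, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 1, 0, 0],
    [1, 0, 0, 0, 0, 0, 0, 0],
    [0, 1, 1, 0, 0, 0, 0, 1],
    [1, 0, 0, 0, 0, 1, 1, 0],
    [0, 0, 0, 0, 0, 0, 0, 1],
    [0, 0, 1, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 1, 0],
]


def test_compose_rules_of_toy_cascade_and_inverter():
    composed = compose_rules(scheme("example"))
    assert composed.variable_names == ("x1", "x2", "y1")
    assert (composed.p, composed.q) == (0, 0)
    # f(x1, x2, y1) = (y1, x1, !x2)
    from ioboolnet.expr import parse_expr
    names = composed.variable_names
    for rule, etext in zip(composed.update_rules, ["y1", "x1", "!x2"]):
        assert np.array_equal(truth_table_of(rule, names),
                              truth_table_of(parse_expr(etext), names))


def test_full_graph_matches_printed_eight_by_eight_adjacency():
    full = build_full_graph(scheme("example"))
    assert full.to_dense().tolist() == EXAMPLE2_G


def test_composition_routes_agree_on_the_toy_scheme():
    s = scheme("example")
    via_rules = build_transition_graph(compose_rules(s), ())
    via_kron = build_full_graph(s)
    assert (via_rules.adjacency != via_kron.adjacency).nnz == 0


def test_output_indicator_examples():
    m = load_fixture("example1_A")
    assert output_indicator(m, (0,)).tolist() == [True, False, True, False]
    assert output_indicator(m, (1,)).tolist() == [False, True, False, True]
    closed = parse_module("module c\nx1* = x1\n")
    assert output_indicator(closed, ()).all()         # q = 0 -> identity


def test_output_indicators_partition_states(rng):
    for _ in range(10):
        m = random_module(4, 1, 2, 2.0, rng)
        total = np.zeros(2 ** 4, dtype=int)
        for alpha in input_profiles(m.q):
            total += output_indicator(m, alpha).astype(int)
        assert (total == 1).all()


def test_wiring_validation_errors():
    a = load_fixture("example1_A")
    b = load_fixture("example2_B")
    # unwired input
    with pytest.raises(WiringError, match="not wired"):
        InterconnectionScheme((a, b), {(1, "v"): (0, "y")})
    # self-wiring rejected
    with pytest.raises(WiringError, match="own output"):
        InterconnectionScheme((a, b), {(0, "u"): (0, "y"),
                                       (1, "v"): (0, "y")})
    # dimension mismatch in the identity helper
    c = random_module(3, 2, 1, 2.0, np.random.default_rng(1))
    with pytest.raises(WiringError, match="mismatch"):
        two_module_scheme(a, c)


def test_identity_dynamics_compose_to_empty_arc_set():
    a = parse_module("module a\ninputs: u\nx1* = x1\noutput y = x1\n")
    b = parse_module("module b\ninputs: v\ny1* = y1\noutput w = y1\n")
    full = build_full_graph(two_module_scheme(a, b))
    assert full.arc_count == 0


def test_kron_and_rule_composition_agree_on_random_schemes(rng):
    """Graph-level and rule-level composition build the same digraph."""
    for _ in range(30):
        s = random_two_module_scheme(
            int(rng.integers(2, 4)), int(rng.integers(2, 4)),
            float(rng.uniform(1, 3)), rng)
        via_kron = build_full_graph(s)
        via_rules = build_transition_graph(compose_rules(s), ())
        assert (via_kron.adjacency != via_rules.adjacency).nnz == 0
        # every arc changes exactly one module's state, by exactly one bit
        coo = via_kron.adjacency.tocoo()
        diff = coo.row ^ coo.col
        assert np.all(diff > 0)
        assert np.all((diff & (diff - 1)) == 0)


def test_multi_module_composition_dimensions():
    rng = np.random.default_rng(7)
    mods = [random_module(3, 1, 1, 2.0, rng, name=f"m{i}",
                          prefix=f"m{i}_") for i in range(3)]
    wiring = {(0, mods[0].input_names[0]): (2, mods[2].output_names[0]),
              (1, mods[1].input_names[0]): (0, mods[0].output_names[0]),
              (2, mods[2].input_names[0]): (1, mods[1].output_names[0])}
    s = InterconnectionScheme(tuple(mods), wiring)
    composed = compose_rules(s)
    assert composed.n == 9 and composed.p == 0 and composed.q == 0
    full = build_full_graph(s)
    assert full.n_states == 2 ** 9
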