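"""Incidence weights, edge probabilities and the condensed Markov chain."""

import numpy as np
import pytest

from ioboolnet.asymptotic import build_asymptotic_graph
from ioboolnet.fixtures import scheme
from ioboolnet.graphs import ModuleAnalysis
from ioboolnet.probability import (attractor_probabilities, condense_chain,
                                   edge_probabilities, effective_rho,
                                   incidence_weights, relative_probabilities,
                                   switch_probabilities)
from ioboolnet.random_nets import random_two_module_scheme


@pytest.fixture(scope="module")
def example_graph():
    return build_asymptotic_graph(scheme("example"))


def test_uniform_weights(example_graph):
    w = incidence_weights(example_graph.analyses[0], "uniform")
    assert np.allclose(w, [0.5, 0.5])


def test_user_weights_are_validated(example_graph):
    analysis = example_graph.analyses[0]
    assert np.allclose(
        incidence_weights(analysis, np.array([0.3, 0.7])), [0.3, 0.7])
    with pytest.raises(ValueError, match="sum"):
        incidence_weights(analysis, np.array([0.3, 0.6]))
    with pytest.raises(ValueError, match="negative"):
        incidence_weights(analysis, np.array([-0.2, 1.2]))
    with pytest.raises(ValueError, match="expected"):
        incidence_weights(analysis, np.array([1.0]))


def test_single_attractor_set_gets_weight_one():
    analysis = ModuleAnalysis(scheme("yeast_M").modules[1])
    # cell-size module: one fixed point per input profile
    w = incidence_weights(analysis, "basin")
    assert len(w) == 2 and np.allclose(w.sum(), 1.0)
    assert np.allclose(w, [0.5, 0.5])


def test_switch_probabilities_normalize_over_reachable_sets():
    w = np.array([0.25, 0.25, 0.5])
    assert switch_probabilities(w, [2]) == {2: 1.0}
    s = switch_probabilities(w, [1, 2])
    assert s[1] == pytest.approx(0.5) and s[2] == pytest.approx(0.5)
    s = switch_probabilities(w, [1, 3])
    assert s[1] == pytest.approx(1 / 3) and s[3] == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        switch_probabilities(w, [])


def test_effective_rho_cases():
    assert effective_rho(False, True, 0.3) == 0.0    # only B-side switches
    assert effective_rho(True, False, 0.3) == 1.0    # only A-side switches
    assert effective_rho(True, True, 0.3) == 0.3     # mixed
    assert effective_rho(False, False, 0.3) is None  # absorbing vertex


def test_example3_forced_transitions(example_graph):
    """Each vertex of the toy cycle has exactly one outgoing arc with
    probability one (the effective rho degenerates to 0 or 1)."""
    pg = edge_probabilities(example_graph, rho_A=0.5)
    outgoing = {}
    for (src, dst), p in pg.edge_probs.items():
        outgoing.setdefault(src, []).append((dst, p))
    for src, arcs in outgoing.items():
        assert len(arcs) == 1
        assert arcs[0][1] == pytest.approx(1.0)
    assert np.allclose(pg.row_sums(), 1.0)
    assert all(r in (0.0, 1.0) for r in pg.effective_rho)


def test_rows_are_stochastic_on_random_schemes(rng):
    for _ in range(15):
        s = random_two_module_scheme(
            int(rng.integers(2, 5)), int(rng.integers(2, 5)),
            float(rng.uniform(1, 3)), rng)
        g = build_asymptotic_graph(s)
        pg = edge_probabilities(g, rho_A=float(rng.uniform(0.1, 0.9)))
        assert np.allclose(pg.row_sums(), 1.0)
        chain = condense_chain(pg)
        assert np.allclose(chain.M.sum(axis=1), 1.0)
        # absorbing rows are unit vectors
        t = chain.m - chain.r
        assert np.allclose(chain.M[t:, t:], np.eye(chain.r))
        if t:
            assert np.allclose(chain.M_absorp.sum(axis=1), 1.0)
        p_rel = relative_probabilities(chain)
        assert p_rel.sum() == pytest.approx(1.0)


def test_single_scc_chain_is_trivially_absorbing(example_graph):
    pg = edge_probabilities(example_graph, rho_A=0.5)
    chain = condense_chain(pg)
    assert chain.m == chain.r == 1
    assert relative_probabilities(chain)[0] == pytest.approx(1.0)


def test_no_transients_means_p_rel_equals_incidence():
    g = build_asymptotic_graph(scheme("yeast_G1"))
    pg = edge_probabilities(g, 0.5, "uniform", "uniform")
    chain = condense_chain(pg)
    p_rel = relative_probabilities(chain)
    t = chain.m - chain.r
    # with transients absent the sum in the formula is empty
    if t == 0:
        assert np.allclose(p_rel, chain.P_C)
    else:
        absorbed = chain.M_absorp.T @ chain.P_C[:t]
        assert np.allclose(p_rel, chain.P_C[t:] + absorbed)


def test_absorption_matrix_agrees_with_monte_carlo(rng):
    """(I-Q)^-1 R against empirical absorption frequencies of random walks
    simulated directly on the condensed chain (independent oracle)."""
    s = random_two_module_scheme(4, 4, 2.0, rng)
    g = build_asymptotic_graph(s)
    pg = edge_probabilities(g, rho_A=0.4, weights_a="basin",
                            weights_b="basin")
    chain = condense_chain(pg)
    t = chain.m - chain.r
    if t == 0:
        pytest.skip("sampled chain has no transient components")
    n_walks = 100_000
    for start in range(min(t, 3)):
        state = np.full(n_walks, start)
        active = np.ones(n_walks, dtype=bool)
        absorbed = np.full(n_walks, -1)
        for _ in range(10_000):
            if not active.any():
                break
            probs = chain.M[state[active]]
            u = rng.random(active.sum())
            nxt = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            state[active] = nxt
            done = nxt >= t
            idx = np.nonzero(active)[0]
            absorbed[idx[done]] = nxt[done] - t
            active[idx[done]] = False
        assert not active.any()
        freq = np.bincount(absorbed, minlength=chain.r) / n_walks
        se = np.sqrt(np.maximum(freq * (1 - freq), 1e-6) / n_walks)
        assert np.all(np.abs(freq - chain.M_absorp[start]) <= 3 * se + 1e-3)


def test_mammalian_p_rel_is_rho_independent():
    g = build_asymptotic_graph(scheme("mammal"))
    values = []
    for rho in (0.2, 0.5, 0.6, 0.7):
        pr = attractor_probabilities(g, rho_A=rho, weights_a="basin",
                                     weights_b="basin")
        values.append(sorted(round(v, 9) for v in pr.values()))
    assert all(v == values[0] for v in values)
    assert values[0] == [pytest.approx(1 / 3), pytest.approx(2 / 3)]


def test_invalid_rho_rejected(example_graph):
    with pytest.raises(ValueError):
        edge_probabilities(example_graph, rho_A=1.5)
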