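"""Shared fixtures and brute-force oracles for the test suite."""

import numpy as np
import pytest
import scipy.sparse as sp

from ioboolnet.fixtures import load_fixture, scheme
from ioboolnet.graphs import ModuleAnalysis


def transitive_closure(dense: np.ndarray) -> np.ndarray:
    """Reachability oracle by repeated boolean matrix multiplication."""
    n = dense.shape[0]
    reach = dense.astype(bool) | np.eye(n, dtype=bool)
    for _ in range(n):
        nxt = reach @ reach
        if (nxt == reach).all():
            break
        reach = nxt
    return reach


def brute_force_sccs(dense: np.ndarray):
    """SCCs via mutual reachability on the transitive closure."""
    reach = transitive_closure(dense)
    mutual = reach & reach.T
    seen = set()
    comps = []
    for v in range(dense.shape[0]):
        if v in seen:
            continue
        comp = frozenset(np.nonzero(mutual[v])[0].tolist())
        seen |= comp
        comps.append(comp)
    return comps


def brute_force_attractors(dense: np.ndarray):
    """Terminal SCCs of a dense adjacency matrix, as frozensets."""
    comps = brute_force_sccs(dense)
    out = []
    for comp in comps:
        members = sorted(comp)
        leaves = True
        for v in members:
            for w in np.nonzero(dense[v])[0]:
                if w not in comp:
                    leaves = False
                    break
            if not leaves:
                break
        if leaves:
            out.append(frozenset(members))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def clock_analysis():
    return ModuleAnalysis(load_fixture("clock7"))


@pytest.fixture(scope="session")
def mammal_analysis():
    return ModuleAnalysis(load_fixture("mammal_cc10"))


@pytest.fixture(scope="session")
def yeast_M_graph():
    from ioboolnet.asymptotic import build_asymptotic_graph
    return build_asymptotic_graph(scheme("yeast_M"))
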