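"""Random IO Boolean networks with controlled mean connectivity.

An NK-style generator adapted to modules with inputs and outputs.  The
wiring diagram is drawn first as a dependency matrix: each output depends
on exactly one uniformly chosen state variable; each update rule draws its
number of essential arguments ``k_i`` from a Binomial(n+p, K_mean/(n+p))
and then a uniform ``k_i``-subset of the input and state variables; the
whole draw is repeated until every input column is used.  Boolean functions
are then sampled uniformly among the functions that depend *essentially* on
all their declared arguments, so the realized connectivity matches the
dependency matrix exactly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import IOBooleanModule, DEFAULT_STATE_CAP
from .expr import TruthTable
from .interconnect import InterconnectionScheme, two_module_scheme


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class DependencyMatrix:
    """Wiring diagram of an (n, p, q) module.

    ``A`` (n x p) holds input dependencies, ``B`` (n x n) state
    dependencies and ``D`` (q x n) output dependencies; ``C = [A|B]`` has
    exactly ``k[i]`` ones in row ``i``.
    """

    A: np.ndarray
    B: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        n = self.B.shape[0]
        if self.B.shape != (n, n) or self.A.shape[0] != n:
            raise GeneratorError("inconsistent dependency matrix shapes")
        if self.D.size and self.D.shape[1] != n:
            raise GeneratorError("inconsistent dependency matrix shapes")
        if self.A.shape[1] and not self.A.any(axis=0).all():
            raise GeneratorError("every input column must be non-zero")
        if self.D.size and not (self.D.sum(axis=1) == 1).all():
            raise GeneratorError("each output row must have exactly one 1")

    @property
    def C(self) -> np.ndarray:
        return np.concatenate([self.A, self.B], axis=1)

    @property
    def k(self) -> np.ndarray:
        return self.C.sum(axis=1)

    @property
    def shape(self) -> Tuple[int, int]:
        """(n + q) x (p + n), the full wiring-diagram matrix shape."""
        n, p = self.B.shape[0], self.A.shape[1]
        return (n + self.D.shape[0], p + n)


def random_dependency_matrix(n: int, p: int, q: int, k_mean: float,
                             rng: np.random.Generator,
                             max_retries: int = 1000) -> DependencyMatrix:
    """Draw a dependency matrix with Binomial(n+p, K_mean/(n+p)) row sums.

    The subset draw is repeated wholesale until every column of the input
    block is non-zero, as the procedure prescribes; the row sums ``k_i``
    are redrawn only if the check cannot succeed (sum of k_i below p) or
    after ``max_retries`` failures.
    """
    if n < 1 or p < 0 or q < 0:
        raise GeneratorError("need n >= 1, p >= 0, q >= 0")
    if not 1 <= k_mean <= n + p:
        raise GeneratorError("K_mean must lie in [1, n + p]")
    D = np.zeros((q, n), dtype=bool)
    for i in range(q):
        D[i, rng.integers(n)] = True
    while True:
        k = rng.binomial(n + p, k_mean / (n + p), size=n)
        if p and k.sum() < p:
            continue    # no subset assignment can use every input
        for _ in range(max_retries):
            C = np.zeros((n, n + p), dtype=bool)
            for i in range(n):
                cols = rng.choice(n + p, size=k[i], replace=False)
                C[i, cols] = True
            if not p or C[:, :p].any(axis=0).all():
                return DependencyMatrix(A=C[:, :p], B=C[:, p:], D=D)


def _nondegenerate_tables(k: int) -> np.ndarray:
    """All truth tables of k arguments with every argument essential.

    Enumerated once per arity and cached; used for k <= 4 (65,536 tables).
    """
    if k not in _nondegenerate_tables._cache:
        size = 2 ** k
        tables = np.arange(2 ** size, dtype=np.uint32)
        bits = ((tables[:, None] >> np.arange(size)) & 1).astype(bool)
        keep = np.ones(len(tables), dtype=bool)
        rows = np.arange(size)
        for pos in range(k):
            flipped = rows ^ (1 << (k - 1 - pos))
            keep &= (bits[:, rows] != bits[:, flipped]).any(axis=1)
        _nondegenerate_tables._cache[k] = bits[keep]
    return _nondegenerate_tables._cache[k]


_nondegenerate_tables._cache = {}


def _is_essential_all(table: np.ndarray, k: int) -> bool:
    rows = np.arange(2 ** k)
    for pos in range(k):
        flipped = rows ^ (1 << (k - 1 - pos))
        if not (table[rows] != table[flipped]).any():
            return False
    return True


def _random_function(k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform truth table with all k arguments essential (k = 0: constant)."""
    if k == 0:
        return np.array([bool(rng.integers(2))])
    if k <= 4:
        tables = _nondegenerate_tables(k)
        return tables[rng.integers(len(tables))].copy()
    while True:   # rejection; degenerate tables are rare for k >= 5
        table = rng.integers(2, size=2 ** k).astype(bool)
        if _is_essential_all(table, k):
            return table


def random_functions(dep: DependencyMatrix, rng: np.random.Generator,
                     name: str = "random",
                     prefix: str = "") -> IOBooleanModule:
    """Sample a module whose essential dependencies equal ``dep`` exactly."""
    n, p = dep.B.shape[0], dep.A.shape[1]
    q = dep.D.shape[0]
    inputs = tuple(f"{prefix}u{j + 1}" for j in range(p))
    states = tuple(f"{prefix}x{i + 1}" for i in range(n))
    symbols = inputs + states
    rules = []
    for i in range(n):
        deps = tuple(symbols[j] for j in np.nonzero(dep.C[i])[0])
        rules.append(TruthTable(deps, _random_function(len(deps), rng)))
    outputs = []
    for i in range(q):
        var = states[int(np.nonzero(dep.D[i])[0][0])]
        table = np.array([False, True]) if rng.integers(2) \
            else np.array([True, False])   # identity or negation
        outputs.append(TruthTable((var,), table))
    return IOBooleanModule(
        name=name, variable_names=states, input_names=inputs,
        update_rules=tuple(rules),
        output_names=tuple(f"{prefix}out{i + 1}" for i in range(q)),
        output_rules=tuple(outputs))


def random_module(n: int, p: int, q: int, k_mean: float,
                  rng: np.random.Generator, name: str = "random",
                  prefix: str = "") -> IOBooleanModule:
    """Random (n, p, q) IO module with mean connectivity ``k_mean``."""
    return random_functions(
        random_dependency_matrix(n, p, q, k_mean, rng), rng,
        name=name, prefix=prefix)


def random_two_module_scheme(n_a: int, n_b: int, k_mean: float,
                             rng: np.random.Generator,
                             p: int = 1, q: int = 1) -> InterconnectionScheme:
    """Random identity interconnection of two SISO-style modules."""
    a = random_module(n_a, p, q, min(k_mean, n_a + p), rng, "A", prefix="a_")
    b = random_module(n_b, q, p, min(k_mean, n_b + q), rng, "B", prefix="b_")
    return two_module_scheme(a, b)


def ring_scheme(modules: Sequence[IOBooleanModule]) -> InterconnectionScheme:
    """Four-module ring A -> B -> C -> D -> A with a doubled B <-> C link.

    Dimensions: p_A = q_A = p_D = q_D = 1 and p_B = q_B = p_C = q_C = 2.
    """
    a, b, c, d = modules
    wiring = {
        (1, b.input_names[0]): (0, a.output_names[0]),
        (2, c.input_names[0]): (1, b.output_names[0]),
        (2, c.input_names[1]): (1, b.output_names[1]),
        (1, b.input_names[1]): (2, c.output_names[1]),
        (3, d.input_names[0]): (2, c.output_names[0]),
        (0, a.input_names[0]): (3, d.output_names[0]),
    }
    return InterconnectionScheme((a, b, c, d), wiring)


# ---------------------------------------------------------------------------
# comparison experiments

@dataclass
class ExperimentConfig:
    n_a: int = 10
    n_b: int = 10
    p: int = 2
    q: int = 2
    k_means: Tuple[float, ...] = tuple(range(1, 11))
    replicates: int = 10
    seed: int = 0
    cross_max_vertices: int = 10 ** 6
    full_max_dim: int = 14


def run_comparison_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Compare asymptotic- and cross-graph predictions on random schemes.

    Per replicate: generate a two-module scheme, build the asymptotic graph
    (always), the cross graph and full graph (size permitting), and record
    graph sizes, attractor counts, spurious counts, accuracies and
    per-stage timings.  Partial runs are kept with a status flag.
    """
    from .asymptotic import (asymptotic_attractors, build_asymptotic_graph,
                             classify_spurious)
    from .cross import build_cross_graph, cross_attractors
    from .core import ResourceCapError
    from .graphs import scc_decompose
    from .interconnect import build_full_graph

    rng = np.random.default_rng(config.seed)
    records = []
    for k_mean in config.k_means:
        for rep in range(config.replicates):
            rec: Dict = {"k_mean": k_mean, "replicate": rep,
                         "status": "ok"}
            scheme = random_two_module_scheme(
                config.n_a, config.n_b, k_mean, rng,
                p=config.p, q=config.q)
            t0 = time.perf_counter()
            g_as = build_asymptotic_graph(scheme)
            attrs = asymptotic_attractors(g_as)
            rec["t_asymptotic"] = time.perf_counter() - t0
            rec["N_as"] = g_as.vertex_count
            rec["n_as_attractors"] = len(attrs)

            oracle = None
            t0 = time.perf_counter()
            try:
                cross = build_cross_graph(
                    scheme, analyses=g_as.analyses,
                    max_vertices=config.cross_max_vertices)
                rec["N_cr"] = cross.vertex_count
                oracle = [c.states for c in cross_attractors(
                    cross, expand_limit=None)]
            except ResourceCapError:
                rec["N_cr"] = None
                rec["status"] = "cross_skipped"
            rec["t_cross"] = time.perf_counter() - t0

            if scheme.n_total <= config.full_max_dim:
                t0 = time.perf_counter()
                full = build_full_graph(scheme)
                dec = scc_decompose(full.adjacency)
                full_attrs = sorted(dec.terminal_components(),
                                    key=lambda a: int(a[0]))
                rec["t_full"] = time.perf_counter() - t0
                rec["n_true_attractors"] = len(full_attrs)
                if oracle is None:
                    oracle = full_attrs

            if oracle is not None:
                spurious = 0
                accuracies = []
                for a in attrs:
                    classify_spurious(a, oracle)
                    if a.status == "spurious":
                        spurious += 1
                    else:
                        q_states = oracle[a.matched_attractor]
                        accuracies.append(len(a.pi) / len(q_states))
                rec["n_spurious"] = spurious
                rec["mean_accuracy"] = (float(np.mean(accuracies))
                                        if accuracies else None)
                rec["n_fully_recovered"] = sum(
                    1 for x in accuracies if x == 1.0)
            records.append(rec)
    return pd.DataFrame.from_records(records)
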