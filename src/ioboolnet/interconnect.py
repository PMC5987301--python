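"""Interconnection of IO modules: rule composition and graph composition.

Two (or more) IO modules are interconnected by wiring every input variable
of every module to an output variable of another module (identity
interconnection maps).  The closed composition can be built two equivalent
ways:

* *rule composition*: substitute each input symbol by the wired output
  expression, yielding one closed module over the concatenated state space;
* *graph composition*: combine the modules' per-input transition graphs
  with a Kronecker-product construction gated by diagonal output-indicator
  matrices, a generalization of the Cartesian product of graphs that keeps
  only transitions consistent with the wiring.

Both constructions yield the same transition graph state-for-state, with
the composite state index in module-major order (first module's state most
significant).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .core import (Bits, DEFAULT_STATE_CAP, IOBooleanModule, TransitionGraph,
                   ResourceCapError, build_transition_graph, outputs_table)
from .expr import Expr


class WiringError(ValueError):
    """Invalid interconnection wiring."""


@dataclass(frozen=True)
class InterconnectionScheme:
    """Modules plus a wiring ``(module, input name) -> (module, output name)``.

    Every input of every module must be wired to exactly one output of a
    *different* module; the resulting closed composition has no inputs and
    no outputs.
    """

    modules: Tuple[IOBooleanModule, ...]
    wiring: Mapping[Tuple[int, str], Tuple[int, str]]

    def __post_init__(self):
        if len(self.modules) < 2:
            raise WiringError("an interconnection needs at least two modules")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise WiringError("module names must be distinct")
        for k, mod in enumerate(self.modules):
            for inp in mod.input_names:
                if (k, inp) not in self.wiring:
                    raise WiringError(
                        f"input '{inp}' of module '{mod.name}' is not wired")
        for (k, inp), (src, out) in self.wiring.items():
            mod = self.modules[k]
            if inp not in mod.input_names:
                raise WiringError(
                    f"module '{mod.name}' has no input '{inp}'")
            if not 0 <= src < len(self.modules):
                raise WiringError(f"wiring references unknown module {src}")
            if src == k:
                raise WiringError(
                    f"input '{inp}' of module '{mod.name}' may not be wired "
                    f"to the module's own output")
            if out not in self.modules[src].output_names:
                raise WiringError(
                    f"module '{self.modules[src].name}' has no output '{out}'")

    @property
    def n_total(self) -> int:
        return sum(m.n for m in self.modules)

    def input_profile_of(self, k: int,
                         alphas: Mapping[int, Bits]) -> Bits:
        """Input profile of module ``k`` given every module's output profile."""
        mod = self.modules[k]
        bits = []
        for inp in mod.input_names:
            src, out = self.wiring[(k, inp)]
            pos = self.modules[src].output_names.index(out)
            bits.append(int(alphas[src][pos]))
        return tuple(bits)


def two_module_scheme(a: IOBooleanModule, b: IOBooleanModule
                      ) -> InterconnectionScheme:
    """Identity interconnection of two modules (p_A = q_B, p_B = q_A)."""
    if a.p != b.q or b.p != a.q:
        raise WiringError(
            f"dimension mismatch: ({a.p} inputs vs {b.q} outputs) / "
            f"({b.p} inputs vs {a.q} outputs)")
    wiring: Dict[Tuple[int, str], Tuple[int, str]] = {}
    for i, inp in enumerate(a.input_names):
        wiring[(0, inp)] = (1, b.output_names[i])
    for j, inp in enumerate(b.input_names):
        wiring[(1, inp)] = (0, a.output_names[j])
    return InterconnectionScheme((a, b), wiring)


def compose_rules(scheme: InterconnectionScheme,
                  name: str = None) -> IOBooleanModule:
    """Close the interconnection by rule substitution.

    The composite module has the concatenated state variables (first module
    first) and no inputs or outputs; each input symbol is replaced by the
    wired output expression of its source module.
    """
    all_vars: List[str] = []
    for mod in scheme.modules:
        for v in mod.variable_names:
            if v in all_vars:
                raise WiringError(
                    f"state variable name '{v}' occurs in more than one "
                    f"module; rename before composing")
            all_vars.append(v)
    rules: List[Expr] = []
    for k, mod in enumerate(scheme.modules):
        subst: Dict[str, Expr] = {}
        for inp in mod.input_names:
            src, out = scheme.wiring[(k, inp)]
            src_mod = scheme.modules[src]
            subst[inp] = src_mod.output_rules[src_mod.output_names.index(out)]
        rules.extend(r.substitute(subst) for r in mod.update_rules)
    return IOBooleanModule(
        name=name or "+".join(m.name for m in scheme.modules),
        variable_names=tuple(all_vars),
        input_names=(),
        update_rules=tuple(rules),
    )


def output_indicator(module: IOBooleanModule, alpha: Sequence[int]
                     ) -> np.ndarray:
    """Boolean vector over states: entry i is 1 iff h(state i) == alpha.

    For a module without outputs (q = 0) this is the all-ones vector.
    """
    alpha = tuple(int(b) for b in alpha)
    if len(alpha) != module.q:
        raise ValueError(
            f"output profile has length {len(alpha)}, module has {module.q}")
    tab = outputs_table(module)
    mask = np.ones(2 ** module.n, dtype=bool)
    for j, b in enumerate(alpha):
        mask &= tab[:, j] == bool(b)
    return mask


def kron_compose(scheme: InterconnectionScheme,
                 adjacency_by_input: Sequence[Mapping[Bits, sp.spmatrix]],
                 indicators: Sequence[Mapping[Bits, np.ndarray]]
                 ) -> sp.csr_matrix:
    """Generic Kronecker composition of per-module digraphs.

    ``adjacency_by_input[k][u]`` is module ``k``'s digraph under input
    profile ``u`` (states or projected blocks); ``indicators[k][alpha]`` is
    the diagonal of the output-indicator matrix for output profile
    ``alpha``.  A term is added for every module ``k`` and every assignment
    of output profiles to the other modules: the moving module contributes
    its digraph under the wired input, the fixed modules contribute their
    indicator diagonals.  For two modules this is exactly the gated
    Cartesian-product formula.
    """
    K = len(scheme.modules)
    sizes = [next(iter(adjacency_by_input[k].values())).shape[0]
             for k in range(K)]
    total: sp.csr_matrix = None
    alpha_choices = [sorted(indicators[j].keys()) for j in range(K)]
    for k in range(K):
        others = [j for j in range(K) if j != k]
        for combo in product(*(alpha_choices[j] for j in others)):
            alphas = dict(zip(others, combo))
            u = scheme.input_profile_of(k, alphas)
            factors = []
            for j in range(K):
                if j == k:
                    factors.append(
                        adjacency_by_input[k][u].astype(np.int8))
                else:
                    diag = indicators[j][alphas[j]]
                    idx = np.nonzero(diag)[0]
                    factors.append(sp.csr_matrix(
                        (np.ones(len(idx), dtype=np.int8), (idx, idx)),
                        shape=(len(diag), len(diag))))
            term = factors[0]
            for f in factors[1:]:
                term = sp.kron(term, f, format="csr")
            total = term if total is None else (total + term)
    total = (total > 0).astype(bool).tocsr()
    total.eliminate_zeros()
    return total


def build_full_graph(scheme: InterconnectionScheme,
                     cap: int = DEFAULT_STATE_CAP) -> TransitionGraph:
    """Transition graph of the closed interconnection over 2**n_total states.

    For two modules the graph is assembled by the Kronecker composition of
    the per-input module graphs; for more modules it is built from the
    composed rules (the constructions agree where both apply).
    """
    n_total = scheme.n_total
    if n_total > cap:
        raise ResourceCapError(
            f"composite dimension {n_total} exceeds the state-space cap "
            f"{cap}; raise `cap` explicitly to proceed")
    name = "+".join(m.name for m in scheme.modules)
    if len(scheme.modules) == 2:
        from .core import input_profiles
        adjs, inds = [], []
        for mod in scheme.modules:
            adjs.append({u: build_transition_graph(mod, u, cap=cap).adjacency
                         for u in input_profiles(mod.p)})
            inds.append({alpha: output_indicator(mod, alpha)
                         for alpha in input_profiles(mod.q)})
        adj = kron_compose(scheme, adjs, inds)
        return TransitionGraph(name, n_total, (), adj)
    composed = compose_rules(scheme, name=name)
    return build_transition_graph(composed, (), cap=cap)


def composite_index(state_parts: Sequence[int],
                    dims: Sequence[int]) -> int:
    """Composite 0-based state index, first module most significant."""
    idx = 0
    for s, n in zip(state_parts, dims):
        idx = (idx << n) | int(s)
    return idx
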