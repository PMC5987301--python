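"""Input-output asynchronous Boolean networks and their transition graphs.

An IO asynchronous Boolean network has ``n`` state variables, ``p`` input
variables and ``q`` output variables.  Its transition function ``f`` maps an
input profile and a state to the next (synchronous) image; the asynchronous
dynamics flip one disagreeing coordinate at a time.  For a fixed input
profile ``u`` the dynamics are the asynchronous state transition graph over
all ``2**n`` states, with an arc ``x -> x ^ e_i`` for every coordinate ``i``
with ``f_i(u, x) != x_i``.

States are identified with integers: internally 0-based, while all
user-facing reports use the 1-based lexicographic convention (left-most bit
most significant), i.e. ``index - 1 = sum_k x_k 2**(n-k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .expr import Expr, ExprSyntaxError, Var, parse_expr

Bits = Tuple[int, ...]

#: refuse to enumerate state spaces above this dimension by default
DEFAULT_STATE_CAP = 24


class NetworkFormatError(ValueError):
    """Malformed module source (carries the 1-based line number)."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ResourceCapError(RuntimeError):
    """State-space enumeration refused because the dimension exceeds the cap."""


class DimensionError(ValueError):
    """An input/state/output vector has the wrong length."""


@dataclass(frozen=True)
class IOBooleanModule:
    """An IO asynchronous Boolean network (n state, p input, q output vars)."""

    name: str
    variable_names: Tuple[str, ...]
    input_names: Tuple[str, ...]
    update_rules: Tuple[Expr, ...]
    output_names: Tuple[str, ...] = ()
    output_rules: Tuple[Expr, ...] = ()

    def __post_init__(self):
        if len(self.variable_names) < 1:
            raise ValueError("a module needs at least one state variable")
        if len(self.update_rules) != len(self.variable_names):
            raise ValueError("one update rule per state variable required")
        if len(self.output_rules) != len(self.output_names):
            raise ValueError("one output rule per output name required")
        declared = list(self.input_names) + list(self.variable_names)
        seen = set()
        for nm in declared:
            if nm in seen:
                raise ValueError(f"duplicate variable name '{nm}'")
            seen.add(nm)
        allowed = frozenset(declared)
        states = frozenset(self.variable_names)
        for nm, rule in zip(self.variable_names, self.update_rules):
            bad = rule.refs() - allowed
            if bad:
                raise ValueError(
                    f"update rule for '{nm}' references undeclared "
                    f"symbol(s) {sorted(bad)}")
        for nm, rule in zip(self.output_names, self.output_rules):
            bad = rule.refs() - states
            if bad:
                extra = rule.refs() & frozenset(self.input_names)
                if extra:
                    raise ValueError(
                        f"output rule for '{nm}' may not read input(s) "
                        f"{sorted(extra)}")
                raise ValueError(
                    f"output rule for '{nm}' references undeclared "
                    f"symbol(s) {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.variable_names)

    @property
    def p(self) -> int:
        return len(self.input_names)

    @property
    def q(self) -> int:
        return len(self.output_names)


# ---------------------------------------------------------------------------
# state indexing

def state_to_index(bits: Sequence[int]) -> int:
    """1-based lexicographic index of a state (left-most bit most significant)."""
    i = 0
    for b in bits:
        i = (i << 1) | (1 if b else 0)
    return i + 1


def index_to_state(index: int, n: int) -> Bits:
    """Inverse of :func:`state_to_index` for a module of dimension ``n``."""
    if not 1 <= index <= 2 ** n:
        raise IndexError(f"state index {index} out of range 1..2^{n}")
    v = index - 1
    return tuple((v >> (n - 1 - k)) & 1 for k in range(n))


def bits_to_int(bits: Sequence[int]) -> int:
    """Internal 0-based integer encoding of a state."""
    return state_to_index(bits) - 1


def int_to_bits(value: int, n: int) -> Bits:
    return index_to_state(value + 1, n)


def bitstring(value: int, n: int) -> str:
    return format(value, f"0{n}b")


def state_table(n: int) -> np.ndarray:
    """(2**n, n) boolean array: row ``i`` is the bit vector of state ``i``."""
    idx = np.arange(2 ** n, dtype=np.int64)
    cols = [((idx >> (n - 1 - k)) & 1).astype(bool) for k in range(n)]
    return np.stack(cols, axis=1)


def input_profiles(p: int) -> List[Bits]:
    """All input profiles in ascending lexicographic (integer) order."""
    return [tuple(int(b) for b in format(v, f"0{p}b")) if p else ()
            for v in range(2 ** p)]


def profile_int(profile: Bits) -> int:
    return bits_to_int(profile) if profile else 0


# ---------------------------------------------------------------------------
# rule evaluation

def _check_profile(module: IOBooleanModule, u: Sequence[int]) -> Bits:
    u = tuple(int(b) for b in u)
    if len(u) != module.p:
        raise DimensionError(
            f"input profile has length {len(u)}, module expects {module.p}")
    return u


def _env_for_states(module: IOBooleanModule, u: Bits) -> Dict[str, np.ndarray]:
    X = state_table(module.n)
    env = {nm: X[:, k] for k, nm in enumerate(module.variable_names)}
    env.update({nm: bool(b) for nm, b in zip(module.input_names, u)})
    return env


def evaluate_update(module: IOBooleanModule, u: Sequence[int]) -> np.ndarray:
    """(2**n, n) boolean array of the synchronous image f(u, x) for all x."""
    u = _check_profile(module, u)
    env = _env_for_states(module, u)
    cols = []
    for rule in module.update_rules:
        out = rule.evaluate(env)
        if not isinstance(out, np.ndarray):
            out = np.full(2 ** module.n, bool(out))
        cols.append(out)
    return np.stack(cols, axis=1)


def outputs_table(module: IOBooleanModule) -> np.ndarray:
    """(2**n, q) boolean array of output profiles h(x) for all states."""
    X = state_table(module.n)
    env = {nm: X[:, k] for k, nm in enumerate(module.variable_names)}
    cols = []
    for rule in module.output_rules:
        out = rule.evaluate(env)
        if not isinstance(out, np.ndarray):
            out = np.full(2 ** module.n, bool(out))
        cols.append(out)
    if not cols:
        return np.zeros((2 ** module.n, 0), dtype=bool)
    return np.stack(cols, axis=1)


def output_ints(module: IOBooleanModule) -> np.ndarray:
    """Per-state output profile packed as an integer (lexicographic)."""
    tab = outputs_table(module)
    q = module.q
    out = np.zeros(2 ** module.n, dtype=np.int64)
    for j in range(q):
        out |= tab[:, j].astype(np.int64) << (q - 1 - j)
    return out


def output_of_state(module: IOBooleanModule, x: Sequence[int]) -> Bits:
    x = tuple(int(b) for b in x)
    if len(x) != module.n:
        raise DimensionError(
            f"state has length {len(x)}, module dimension is {module.n}")
    env = {nm: bool(b) for nm, b in zip(module.variable_names, x)}
    return tuple(int(bool(r.evaluate(env))) for r in module.output_rules)


def successors(module: IOBooleanModule, u: Sequence[int],
               x: Sequence[int]) -> set:
    """Asynchronous successors of a single state (empty iff fixed point)."""
    u = _check_profile(module, u)
    x = tuple(int(b) for b in x)
    if len(x) != module.n:
        raise DimensionError(
            f"state has length {len(x)}, module dimension is {module.n}")
    env = {nm: bool(b) for nm, b in zip(module.variable_names, x)}
    env.update({nm: bool(b) for nm, b in zip(module.input_names, u)})
    out = set()
    for k, rule in enumerate(module.update_rules):
        if int(bool(rule.evaluate(env))) != x[k]:
            flipped = list(x)
            flipped[k] = 1 - flipped[k]
            out.add(tuple(flipped))
    return out


# ---------------------------------------------------------------------------
# transition graphs

@dataclass(frozen=True)
class TransitionGraph:
    """Asynchronous state transition graph of one module under one input.

    ``adjacency`` is a boolean CSR matrix with entry (i, j) = 1 iff state j
    is a successor of state i (0-based internal indices).
    """

    module_name: str
    n: int
    input_profile: Bits
    adjacency: sp.csr_matrix

    @property
    def n_states(self) -> int:
        return 2 ** self.n

    @property
    def arc_count(self) -> int:
        return int(self.adjacency.nnz)

    def successors_of(self, state: int) -> np.ndarray:
        """Sorted 0-based successor indices of an internal state index."""
        row = self.adjacency.indices[
            self.adjacency.indptr[state]:self.adjacency.indptr[state + 1]]
        return np.sort(row)

    def successor_sets(self):
        """Iterate successor index arrays for states 0..2**n-1."""
        for i in range(self.n_states):
            yield self.successors_of(i)

    def to_dense(self) -> np.ndarray:
        return self.adjacency.toarray().astype(np.int8)


def build_transition_graph(module: IOBooleanModule, u: Sequence[int],
                           cap: int = DEFAULT_STATE_CAP) -> TransitionGraph:
    """Build the asynchronous transition graph of ``module`` under input ``u``."""
    if module.n > cap:
        raise ResourceCapError(
            f"module dimension {module.n} exceeds the state-space cap {cap}; "
            f"raise `cap` explicitly to proceed")
    u = _check_profile(module, u)
    n = module.n
    F = evaluate_update(module, u)
    X = state_table(n)
    toggle = F != X
    srcs, dsts = [], []
    for k in range(n):
        rows = np.nonzero(toggle[:, k])[0]
        srcs.append(rows)
        dsts.append(rows ^ (1 << (n - 1 - k)))
    if srcs:
        src = np.concatenate(srcs)
        dst = np.concatenate(dsts)
    else:  # pragma: no cover - n >= 1 always
        src = dst = np.empty(0, dtype=np.int64)
    adj = sp.csr_matrix(
        (np.ones(len(src), dtype=bool), (src, dst)),
        shape=(2 ** n, 2 ** n))
    return TransitionGraph(module.name, n, u, adj)


# ---------------------------------------------------------------------------
# the plain-text network format

def parse_module(text: str, name_hint: str = "module") -> IOBooleanModule:
    """Parse the plain-text rule format.

    Format, one construct per line (``#`` starts a comment)::

        module <name>
        inputs: u1, u2
        X* = <expr>
        output <name> = <expr>

    Variable order in the file fixes bit order, left-most (first declared)
    bit most significant.
    """
    name = name_hint
    input_names: List[str] = []
    variable_names: List[str] = []
    update_rules: List[Expr] = []
    output_names: List[str] = []
    output_rules: List[Expr] = []
    saw_inputs = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("module "):
            name = line[len("module "):].strip()
            if not name:
                raise NetworkFormatError("missing module name", lineno)
            continue
        if line.startswith("inputs:"):
            if saw_inputs:
                raise NetworkFormatError("duplicate inputs line", lineno)
            saw_inputs = True
            names = [s.strip() for s in line[len("inputs:"):].split(",")
                     if s.strip()]
            input_names.extend(names)
            continue
        if line.startswith("output "):
            rest = line[len("output "):]
            if "=" not in rest:
                raise NetworkFormatError("output line needs '='", lineno)
            oname, etext = rest.split("=", 1)
            try:
                rule = parse_expr(etext.strip())
            except ExprSyntaxError as e:
                raise NetworkFormatError(str(e), lineno) from e
            output_names.append(oname.strip())
            output_rules.append(rule)
            continue
        if "*" in line and "=" in line:
            vpart, etext = line.split("=", 1)
            vname = vpart.strip()
            if not vname.endswith("*"):
                raise NetworkFormatError(
                    "state rule must be written 'X* = <expr>'", lineno)
            vname = vname[:-1].strip()
            try:
                rule = parse_expr(etext.strip())
            except ExprSyntaxError as e:
                raise NetworkFormatError(str(e), lineno) from e
            variable_names.append(vname)
            update_rules.append(rule)
            continue
        raise NetworkFormatError(f"unrecognized line: {line!r}", lineno)

    try:
        return IOBooleanModule(
            name=name,
            variable_names=tuple(variable_names),
            input_names=tuple(input_names),
            update_rules=tuple(update_rules),
            output_names=tuple(output_names),
            output_rules=tuple(output_rules),
        )
    except ValueError as e:
        raise NetworkFormatError(str(e), 0) from e


def serialize_module(module: IOBooleanModule) -> str:
    """Render a module back to the plain-text format (parse round-trips)."""
    lines = [f"module {module.name}"]
    if module.input_names:
        lines.append("inputs: " + ", ".join(module.input_names))
    for nm, rule in zip(module.variable_names, module.update_rules):
        lines.append(f"{nm}* = {rule.to_text()}")
    for nm, rule in zip(module.output_names, module.output_rules):
        lines.append(f"output {nm} = {rule.to_text()}")
    return "\n".join(lines) + "\n"
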