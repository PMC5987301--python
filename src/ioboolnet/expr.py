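"""Boolean expression trees for update and output rules.

The rule language deliberately supports only negation ``!``, conjunction
``&``, disjunction ``|``, parentheses and the literals ``0``/``1`` --
exactly what the shipped biological models need.  Richer operators (xor,
implication) are rejected at parse time.

Expressions evaluate against an environment mapping symbol names to either
python bools or numpy boolean arrays, so a single rule can be evaluated for
one state or vectorised over an entire state space in one call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Tuple, Union

import numpy as np

BoolLike = Union[bool, np.bool_, np.ndarray]


class ExprSyntaxError(ValueError):
    """Raised when a rule cannot be parsed; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class Expr:
    """Base class for Boolean expression nodes (immutable)."""

    __slots__ = ()

    def refs(self) -> FrozenSet[str]:
        """Names of all symbols referenced by the expression."""
        raise NotImplementedError

    def evaluate(self, env: Mapping[str, BoolLike]) -> BoolLike:
        raise NotImplementedError

    def substitute(self, mapping: Mapping[str, "Expr"]) -> "Expr":
        """Return a copy with every symbol in ``mapping`` replaced."""
        raise NotImplementedError

    def to_text(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_text()


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def refs(self):
        return frozenset({self.name})

    def evaluate(self, env):
        try:
            return env[self.name]
        except KeyError:
            raise KeyError(f"undeclared symbol '{self.name}'") from None

    def substitute(self, mapping):
        return mapping.get(self.name, self)

    def to_text(self):
        return self.name


@dataclass(frozen=True)
class Const(Expr):
    value: bool

    def refs(self):
        return frozenset()

    def evaluate(self, env):
        return self.value

    def substitute(self, mapping):
        return self

    def to_text(self):
        return "1" if self.value else "0"


@dataclass(frozen=True)
class Not(Expr):
    arg: Expr

    def refs(self):
        return self.arg.refs()

    def evaluate(self, env):
        v = self.arg.evaluate(env)
        return ~v if isinstance(v, np.ndarray) else not v

    def substitute(self, mapping):
        return Not(self.arg.substitute(mapping))

    def to_text(self):
        inner = self.arg.to_text()
        if isinstance(self.arg, (And, Or)):
            return f"!({inner})"
        return f"!{inner}"


@dataclass(frozen=True)
class And(Expr):
    args: Tuple[Expr, ...]

    def __post_init__(self):
        # keep conjunctions flat so structural equality matches semantics
        # of the associative operator (parse/serialize round trips)
        if any(isinstance(a, And) for a in self.args):
            flat = []
            for a in self.args:
                flat.extend(a.args if isinstance(a, And) else (a,))
            object.__setattr__(self, "args", tuple(flat))

    def refs(self):
        return frozenset().union(*(a.refs() for a in self.args))

    def evaluate(self, env):
        out = self.args[0].evaluate(env)
        for a in self.args[1:]:
            out = out & a.evaluate(env)
        return out

    def substitute(self, mapping):
        return And(tuple(a.substitute(mapping) for a in self.args))

    def to_text(self):
        parts = []
        for a in self.args:
            t = a.to_text()
            if isinstance(a, Or):
                t = f"({t})"
            parts.append(t)
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(Expr):
    args: Tuple[Expr, ...]

    def __post_init__(self):
        if any(isinstance(a, Or) for a in self.args):
            flat = []
            for a in self.args:
                flat.extend(a.args if isinstance(a, Or) else (a,))
            object.__setattr__(self, "args", tuple(flat))

    def refs(self):
        return frozenset().union(*(a.refs() for a in self.args))

    def evaluate(self, env):
        out = self.args[0].evaluate(env)
        for a in self.args[1:]:
            out = out | a.evaluate(env)
        return out

    def substitute(self, mapping):
        return Or(tuple(a.substitute(mapping) for a in self.args))

    def to_text(self):
        return " | ".join(a.to_text() for a in self.args)


class TruthTable(Expr):
    """A Boolean function given extensionally by its truth table.

    Used by the random-network generator, where functions are sampled as
    raw tables rather than formulas.  ``names`` orders the arguments; the
    table is indexed lexicographically with the left-most argument most
    significant (row ``i`` holds the value for the argument bit pattern of
    ``i``).
    """

    __slots__ = ("names", "table")

    def __init__(self, names: Iterable[str], table: np.ndarray):
        names = tuple(names)
        table = np.asarray(table, dtype=bool)
        if table.shape != (2 ** len(names),):
            raise ValueError("truth table length must be 2**len(names)")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "table", table)

    def refs(self):
        return frozenset(self.names)

    def evaluate(self, env):
        k = len(self.names)
        if k == 0:
            return bool(self.table[0])
        idx = None
        for pos, name in enumerate(self.names):
            bit = env[name]
            shift = k - 1 - pos
            term = (np.asarray(bit, dtype=np.int64) << shift
                    if isinstance(bit, np.ndarray) else int(bit) << shift)
            idx = term if idx is None else idx + term
        if isinstance(idx, np.ndarray):
            return self.table[idx]
        return bool(self.table[idx])

    def substitute(self, mapping):
        if not any(n in mapping for n in self.names):
            return self
        if all(isinstance(mapping.get(n, Var(n)), Var) for n in self.names):
            return TruthTable(
                (mapping.get(n, Var(n)).name for n in self.names), self.table
            )
        return self.to_formula().substitute(mapping)

    def to_formula(self) -> Expr:
        """Disjunctive normal form equivalent (one term per true row)."""
        k = len(self.names)
        if not self.table.any():
            return Const(False)
        if self.table.all():
            return Const(True)
        terms = []
        for row in np.nonzero(self.table)[0]:
            lits = []
            for pos, name in enumerate(self.names):
                bit = (int(row) >> (k - 1 - pos)) & 1
                lits.append(Var(name) if bit else Not(Var(name)))
            terms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def to_text(self):
        return self.to_formula().to_text()

    def __eq__(self, other):
        return (isinstance(other, TruthTable) and self.names == other.names
                and np.array_equal(self.table, other.table))

    def __hash__(self):
        return hash((self.names, self.table.tobytes()))


_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
                       r"|(?P<const>[01])"
                       r"|(?P<op>[!&|()]))")


def _tokenize(text: str):
    pos = 0
    tokens = []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ExprSyntaxError(
                f"unexpected character {stripped[0]!r}", pos)
        if m.group("name"):
            tokens.append(("name", m.group("name"), m.start("name")))
        elif m.group("const"):
            tokens.append(("const", m.group("const"), m.start("const")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


class _Parser:
    """Recursive-descent parser; precedence ``!`` > ``&`` > ``|``."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def advance(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> Expr:
        e = self.parse_or()
        kind, val, pos = self.peek()
        if kind != "end":
            raise ExprSyntaxError(f"unexpected token {val!r}", pos)
        return e

    def parse_or(self) -> Expr:
        args = [self.parse_and()]
        while self.peek()[:2] == ("op", "|"):
            self.advance()
            args.append(self.parse_and())
        return args[0] if len(args) == 1 else Or(tuple(args))

    def parse_and(self) -> Expr:
        args = [self.parse_unary()]
        while self.peek()[:2] == ("op", "&"):
            self.advance()
            args.append(self.parse_unary())
        return args[0] if len(args) == 1 else And(tuple(args))

    def parse_unary(self) -> Expr:
        kind, val, pos = self.peek()
        if (kind, val) == ("op", "!"):
            self.advance()
            return Not(self.parse_unary())
        return self.parse_atom()

    def parse_atom(self) -> Expr:
        kind, val, pos = self.advance()
        if kind == "name":
            return Var(val)
        if kind == "const":
            return Const(val == "1")
        if (kind, val) == ("op", "("):
            e = self.parse_or()
            kind2, val2, pos2 = self.advance()
            if (kind2, val2) != ("op", ")"):
                raise ExprSyntaxError("expected ')'", pos2)
            return e
        raise ExprSyntaxError(f"expected expression, found {val!r}", pos)


def parse_expr(text: str) -> Expr:
    """Parse a rule expression written with ``!``, ``&``, ``|``, ``0``/``1``."""
    return _Parser(text).parse()


def truth_table_of(expr: Expr, names: Tuple[str, ...]) -> np.ndarray:
    """Truth table of ``expr`` over the ordered argument list ``names``."""
    k = len(names)
    idx = np.arange(2 ** k)
    env = {n: ((idx >> (k - 1 - pos)) & 1).astype(bool)
           for pos, n in enumerate(names)}
    out = expr.evaluate(env)
    if not isinstance(out, np.ndarray):
        out = np.full(2 ** k, bool(out))
    return out.astype(bool)


def essential_vars(expr: Expr, names: Tuple[str, ...]) -> FrozenSet[str]:
    """Subset of ``names`` the function actually depends on."""
    tbl = truth_table_of(expr, names)
    k = len(names)
    essential = set()
    for pos, name in enumerate(names):
        shift = k - 1 - pos
        idx = np.arange(2 ** k)
        flipped = idx ^ (1 << shift)
        if np.any(tbl[idx] != tbl[flipped]):
            essential.add(name)
    return frozenset(essential)
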