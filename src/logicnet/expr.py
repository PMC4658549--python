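"""Boolean expression trees.

Expressions are immutable trees over AND / OR / NOT / constants / variables.
They are the carrier for update rules: evaluation, substitution with
constant folding, algebraic normal form (XOR-of-ANDs over GF(2)), and a
canonical serialization used to make rule files diffable.

The simplifier is a fixed local pass (constant folding, flattening,
double negation, duplicate removal, literal-complement cancellation); it
is sound but makes no attempt at full minimization.
"""

from __future__ import annotations

import re
from itertools import product
from typing import Iterable, Mapping

__all__ = [
    "Expr", "Const", "Var", "Not", "And", "Or",
    "parse_expression", "ParseError",
    "canonical_dnf", "truth_table", "essential_support", "exprs_equivalent",
]


class Expr:
    """Base class; nodes are immutable and hashable."""

    __slots__ = ()

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        raise NotImplementedError

    def support(self) -> frozenset[str]:
        raise NotImplementedError

    def substitute(self, mapping: Mapping[str, "int | Expr"]) -> "Expr":
        """Replace variables and re-simplify (constants fold away)."""
        raise NotImplementedError

    def anf(self) -> frozenset[frozenset[str]]:
        """Algebraic normal form: XOR of AND-monomials, as a set of
        variable sets.  The empty monomial is the constant 1."""
        raise NotImplementedError

    # -- operators for test/construction ergonomics -------------------
    def __and__(self, other: "Expr") -> "Expr":
        return And.of(self, other)

    def __or__(self, other: "Expr") -> "Expr":
        return Or.of(self, other)

    def __invert__(self) -> "Expr":
        return Not.of(self)


class Const(Expr):
    __slots__ = ("value",)

    def __init__(self, value: int):
        if value not in (0, 1):
            raise ValueError(f"Boolean constant must be 0 or 1, got {value!r}")
        object.__setattr__(self, "value", int(value))

    def __setattr__(self, *a):  # immutability
        raise AttributeError("Expr nodes are immutable")

    def evaluate(self, assignment):
        return self.value

    def support(self):
        return frozenset()

    def substitute(self, mapping):
        return self

    def anf(self):
        return frozenset() if self.value == 0 else frozenset({frozenset()})

    def __repr__(self):
        return str(self.value)

    def __eq__(self, other):
        return isinstance(other, Const) and other.value == self.value

    def __hash__(self):
        return hash(("const", self.value))


TRUE = Const(1)
FALSE = Const(0)


class Var(Expr):
    __slots__ = ("name",)

    def __init__(self, name: str):
        if not name:
            raise ValueError("variable name must be non-empty")
        object.__setattr__(self, "name", name)

    def __setattr__(self, *a):
        raise AttributeError("Expr nodes are immutable")

    def evaluate(self, assignment):
        try:
            return int(assignment[self.name])
        except KeyError:
            raise KeyError(f"no value supplied for variable {self.name!r}") from None

    def support(self):
        return frozenset({self.name})

    def substitute(self, mapping):
        if self.name in mapping:
            repl = mapping[self.name]
            if isinstance(repl, Expr):
                return repl
            return Const(int(repl))
        return self

    def anf(self):
        return frozenset({frozenset({self.name})})

    def __repr__(self):
        return self.name

    def __eq__(self, other):
        return isinstance(other, Var) and other.name == self.name

    def __hash__(self):
        return hash(("var", self.name))


class Not(Expr):
    __slots__ = ("child",)

    def __init__(self, child: Expr):
        object.__setattr__(self, "child", child)

    def __setattr__(self, *a):
        raise AttributeError("Expr nodes are immutable")

    @staticmethod
    def of(child: Expr) -> Expr:
        if isinstance(child, Const):
            return Const(1 - child.value)
        if isinstance(child, Not):
            return child.child
        return Not(child)

    def evaluate(self, assignment):
        return 1 - self.child.evaluate(assignment)

    def support(self):
        return self.child.support()

    def substitute(self, mapping):
        return Not.of(self.child.substitute(mapping))

    def anf(self):
        return _xor(self.child.anf(), frozenset({frozenset()}))

    def __repr__(self):
        if isinstance(self.child, (Var, Const, Not)):
            return f"!{self.child!r}"
        return f"!({self.child!r})"

    def __eq__(self, other):
        return isinstance(other, Not) and other.child == self.child

    def __hash__(self):
        return hash(("not", self.child))


def _literal_key(e: Expr):
    """(variable-or-None, polarity) for complement detection; None for
    non-literal subtrees."""
    if isinstance(e, Var):
        return (e.name, 1)
    if isinstance(e, Not) and isinstance(e.child, Var):
        return (e.child.name, 0)
    return None


class _NaryMixin:
    """Shared machinery for flattened, order-normalized AND / OR."""

    @classmethod
    def of(cls, *terms: Expr) -> Expr:
        """Smart constructor: flatten, fold constants, dedupe, cancel
        complementary literals, normalize order."""
        absorb, identity = cls._ABSORB, cls._IDENTITY
        flat: list[Expr] = []
        seen: set[Expr] = set()
        stack = list(terms)
        while stack:
            t = stack.pop(0)
            if isinstance(t, Const):
                if t.value == absorb:
                    return Const(absorb)
                continue  # identity element drops out
            if isinstance(t, cls):
                stack[0:0] = list(t.terms)
                continue
            if t in seen:
                continue
            seen.add(t)
            flat.append(t)
        lits = {}
        for t in flat:
            k = _literal_key(t)
            if k is not None:
                name, pol = k
                if (name, 1 - pol) in lits:
                    return Const(absorb)  # x and !x together
                lits[k] = True
        if not flat:
            return Const(identity)
        if len(flat) == 1:
            return flat[0]
        flat.sort(key=repr)
        return cls(tuple(flat))

    def evaluate(self, assignment):
        absorb = self._ABSORB
        for t in self.terms:
            if t.evaluate(assignment) == absorb:
                return absorb
        return 1 - absorb

    def support(self):
        out: frozenset[str] = frozenset()
        for t in self.terms:
            out |= t.support()
        return out

    def substitute(self, mapping):
        return type(self).of(*(t.substitute(mapping) for t in self.terms))

    def __eq__(self, other):
        return type(other) is type(self) and other.terms == self.terms

    def __hash__(self):
        return hash((type(self).__name__, self.terms))


class And(_NaryMixin, Expr):
    __slots__ = ("terms",)
    _ABSORB = 0       # a single 0 forces the result
    _IDENTITY = 1     # empty conjunction

    def __init__(self, terms: tuple[Expr, ...]):
        object.__setattr__(self, "terms", terms)

    def __setattr__(self, *a):
        raise AttributeError("Expr nodes are immutable")

    def anf(self):
        acc = frozenset({frozenset()})
        for t in self.terms:
            acc = _anf_mul(acc, t.anf())
        return acc

    def __repr__(self):
        parts = []
        for t in self.terms:
            if isinstance(t, Or):
                parts.append(f"({t!r})")
            else:
                parts.append(repr(t))
        return " & ".join(parts)


class Or(_NaryMixin, Expr):
    __slots__ = ("terms",)
    _ABSORB = 1
    _IDENTITY = 0

    def __init__(self, terms: tuple[Expr, ...]):
        object.__setattr__(self, "terms", terms)

    def __setattr__(self, *a):
        raise AttributeError("Expr nodes are immutable")

    def anf(self):
        # a | b = a xor b xor ab, folded left to right
        acc: frozenset[frozenset[str]] = frozenset()
        for t in self.terms:
            b = t.anf()
            acc = _xor(_xor(acc, b), _anf_mul(acc, b))
        return acc

    def __repr__(self):
        return " | ".join(repr(t) for t in self.terms)


def _xor(a: frozenset, b: frozenset) -> frozenset:
    return a ^ b


def _anf_mul(a: frozenset, b: frozenset) -> frozenset:
    out: set[frozenset[str]] = set()
    for m1 in a:
        for m2 in b:
            m = m1 | m2
            if m in out:
                out.discard(m)  # mod-2 cancellation
            else:
                out.add(m)
    return frozenset(out)


def evaluate_anf(monomials: frozenset[frozenset[str]],
                 assignment: Mapping[str, int]) -> int:
    acc = 0
    for m in monomials:
        acc ^= int(all(assignment[v] for v in m))
    return acc


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """Raised on malformed rule expressions; carries the offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<op>[&|!()])|(?P<name>[A-Za-z0-9_][A-Za-z0-9_./+\-]*))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ParseError(f"unexpected character {stripped[0]!r}", pos)
        if m.group("op"):
            tokens.append(("op", m.group("op"), m.start("op")))
        else:
            tokens.append(("name", m.group("name"), m.start("name")))
        pos = m.end()
    return tokens


def parse_expression(text: str) -> Expr:
    """Parse an update expression over ``&``, ``|``, ``!``, parentheses,
    constants ``0``/``1`` and gene identifiers.

    Identifiers may contain letters, digits, ``_ . / + -`` (gene symbols
    like ``NKX3.1``, ``IL-6`` or ``AKT/mTOR`` appear verbatim).
    Precedence: ``!`` binds tightest, then ``&``, then ``|``.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ParseError("empty expression", 0)
    expr, idx = _parse_or(tokens, 0)
    if idx != len(tokens):
        raise ParseError(f"unexpected token {tokens[idx][1]!r}", tokens[idx][2])
    return expr


def _parse_or(tokens, idx):
    terms = []
    expr, idx = _parse_and(tokens, idx)
    terms.append(expr)
    while idx < len(tokens) and tokens[idx][:2] == ("op", "|"):
        expr, idx = _parse_and(tokens, idx + 1)
        terms.append(expr)
    return Or.of(*terms), idx


def _parse_and(tokens, idx):
    terms = []
    expr, idx = _parse_atom(tokens, idx)
    terms.append(expr)
    while idx < len(tokens) and tokens[idx][:2] == ("op", "&"):
        expr, idx = _parse_atom(tokens, idx + 1)
        terms.append(expr)
    return And.of(*terms), idx


def _parse_atom(tokens, idx):
    if idx >= len(tokens):
        last = tokens[-1][2] if tokens else 0
        raise ParseError("unexpected end of expression", last)
    kind, value, pos = tokens[idx]
    if kind == "op" and value == "!":
        child, idx = _parse_atom(tokens, idx + 1)
        return Not.of(child), idx
    if kind == "op" and value == "(":
        expr, idx = _parse_or(tokens, idx + 1)
        if idx >= len(tokens) or tokens[idx][:2] != ("op", ")"):
            raise ParseError("unbalanced parenthesis", pos)
        return expr, idx + 1
    if kind == "name":
        if value == "0":
            return FALSE, idx + 1
        if value == "1":
            return TRUE, idx + 1
        return Var(value), idx + 1
    raise ParseError(f"unexpected token {value!r}", pos)


# ---------------------------------------------------------------------------
# Semantic utilities
# ---------------------------------------------------------------------------

def truth_table(expr: Expr, variables: Iterable[str] | None = None) -> tuple[int, ...]:
    """Tuple of outputs over all assignments of ``variables`` (sorted
    syntactic support by default), in lexicographic 0-before-1 order."""
    vs = sorted(expr.support()) if variables is None else list(variables)
    out = []
    for bits in product((0, 1), repeat=len(vs)):
        out.append(expr.evaluate(dict(zip(vs, bits))))
    return tuple(out)


def essential_support(expr: Expr) -> frozenset[str]:
    """Variables the function truly depends on (flipping them can change
    the output somewhere)."""
    vs = sorted(expr.support())
    essential = set()
    for v in vs:
        others = [u for u in vs if u != v]
        for bits in product((0, 1), repeat=len(others)):
            a = dict(zip(others, bits))
            a[v] = 0
            lo = expr.evaluate(a)
            a[v] = 1
            if expr.evaluate(a) != lo:
                essential.add(v)
                break
    return frozenset(essential)


def exprs_equivalent(a: Expr, b: Expr) -> bool:
    """Truth-table equality over the union of supports (exhaustive)."""
    vs = sorted(a.support() | b.support())
    if len(vs) > 20:
        raise ValueError("refusing exhaustive comparison beyond 20 variables")
    return truth_table(a, vs) == truth_table(b, vs)


_CANONICAL_DNF_LIMIT = 10


def canonical_dnf(expr: Expr) -> Expr:
    """Truth-table-canonical form: full DNF (sorted minterms) over the
    sorted *essential* support.  Two expressions with equal truth tables
    canonicalize to the identical tree.  Falls back to the smart-constructor
    normal form when the essential support exceeds 10 variables (still
    deterministic, no longer semantically canonical)."""
    ess = sorted(essential_support(expr))
    if len(ess) > _CANONICAL_DNF_LIMIT:
        return expr.substitute({})  # re-run smart constructors
    pad = {v: 0 for v in expr.support()}  # inessential vars: value irrelevant
    if not ess:
        return Const(expr.evaluate(pad))
    minterms = []
    for bits in product((0, 1), repeat=len(ess)):
        if expr.evaluate({**pad, **dict(zip(ess, bits))}):
            lits = [Var(v) if b else Not.of(Var(v)) for v, b in zip(ess, bits)]
            minterms.append(And.of(*lits))
    return Or.of(*minterms)
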