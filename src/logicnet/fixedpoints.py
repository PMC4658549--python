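"""Exhaustive stable-state detection.

A stable state of a synchronous Boolean model is a state the update map
leaves unchanged.  Writing one *consistency equation* per node,
``f_i(x) = x_i``, the stable states are exactly the joint solutions.
The solver groups equations into blocks of bounded joint support,
enumerates each block's satisfying partial assignments, and patches the
partial solutions together with relational joins on shared variables.
The result is stored compactly as disjoint *cubes* — partial assignments
plus free variables — so the cardinality (which for input-rich models is
astronomically larger than memory) is available without expansion.

A brute-force enumerator over all 2^n states doubles as the independent
oracle for small models.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterator

from .expr import Const, Expr
from .model import BooleanModel

__all__ = [
    "Cube", "CubeSet", "ConsistencyEquation", "Block",
    "SolverCapacityError", "consistency_equations", "decompose",
    "solve", "brute_force_fixed_points",
]

DEFAULT_BUDGET = 25
DEFAULT_ROW_CAP = 2_000_000
BRUTE_FORCE_GUARD = 22


class SolverCapacityError(RuntimeError):
    """An intermediate join outgrew the row cap; raise the cap, lower the
    budget, or fall back to sampling."""


@dataclass(frozen=True)
class Cube:
    """A set of states: ``fixed`` pins some nodes, ``free`` nodes range
    over both values; covers 2^|free| states."""

    fixed: tuple[tuple[str, int], ...]  # sorted (node, value) pairs
    free: frozenset[str]

    @staticmethod
    def make(fixed: dict[str, int], free: set[str] | frozenset[str]) -> "Cube":
        return Cube(tuple(sorted(fixed.items())), frozenset(free))

    @property
    def cardinality(self) -> int:
        return 1 << len(self.free)

    def fixed_dict(self) -> dict[str, int]:
        return dict(self.fixed)

    def contains(self, state: dict[str, int]) -> bool:
        return all(state[n] == v for n, v in self.fixed)


def _gray_states(cube: Cube) -> Iterator[dict[str, int]]:
    base = cube.fixed_dict()
    free = sorted(cube.free)
    k = len(free)
    for i in range(1 << k):
        g = i ^ (i >> 1)  # Gray code: successive states differ in one node
        s = dict(base)
        for j, node in enumerate(free):
            s[node] = (g >> (k - 1 - j)) & 1
        yield s


@dataclass
class CubeSet:
    """Disjoint cubes over a common node universe; the stable-state set."""

    nodes: list[str]
    cubes: list[Cube] = field(default_factory=list)

    @property
    def cardinality(self) -> int:
        return sum(c.cardinality for c in self.cubes)

    @property
    def n_cubes(self) -> int:
        return len(self.cubes)

    def __bool__(self):
        return bool(self.cubes)

    def expand(self, limit: int | None = None) -> Iterator[dict[str, int]]:
        """All states in deterministic order (cube order, Gray code over
        the free variables).  Refuses when the cardinality exceeds
        ``limit``."""
        if limit is not None and self.cardinality > limit:
            raise ValueError(
                f"cardinality {self.cardinality} exceeds expansion limit {limit}")
        for cube in self.cubes:
            yield from _gray_states(cube)

    def ones_count(self, node: str) -> int:
        """Number of covered states in which ``node`` is 1 (exact,
        cube-analytic: a free node contributes half of its cube)."""
        total = 0
        for c in self.cubes:
            if node in c.free:
                total += c.cardinality >> 1
            else:
                total += dict(c.fixed).get(node, 0) * c.cardinality
        return total

    def sample_states(self, n: int, seed: int) -> list[dict[str, int]]:
        """Uniform without-replacement sample of ``n`` states, reproducible
        by ``seed``; returned in ascending global-index order."""
        total = self.cardinality
        if n > total:
            raise ValueError(f"cannot sample {n} from {total} states")
        rng = random.Random(seed)
        if total < (1 << 62):
            indices = sorted(rng.sample(range(total), n))
        else:  # len(range) overflows C ssize_t; rejection-sample instead
            chosen: set[int] = set()
            while len(chosen) < n:
                chosen.add(rng.randrange(total))
            indices = sorted(chosen)
        out = []
        offset = 0
        it = iter(self.cubes)
        cube = next(it)
        for idx in indices:
            while idx >= offset + cube.cardinality:
                offset += cube.cardinality
                cube = next(it)
            local = idx - offset
            s = cube.fixed_dict()
            free = sorted(cube.free)
            for j, node in enumerate(free):
                s[node] = (local >> (len(free) - 1 - j)) & 1
            out.append(s)
        return out

    def contains(self, state: dict[str, int]) -> bool:
        return any(c.contains(state) for c in self.cubes)

    def to_csv(self, path: str | Path) -> None:
        """One row per cube: pinned assignment, free variables, count."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["assignment", "free", "count"])
            for c in self.cubes:
                w.writerow([
                    ";".join(f"{n}={v}" for n, v in c.fixed),
                    ";".join(sorted(c.free)),
                    c.cardinality,
                ])

    def to_state_csv(self, path: str | Path, limit: int = 1 << 20) -> None:
        """Expanded 0/1 matrix, one state per row; guarded by ``limit``."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(self.nodes)
            for s in self.expand(limit=limit):
                w.writerow([s[n] for n in self.nodes])

    @staticmethod
    def from_csv(path: str | Path, nodes: list[str]) -> "CubeSet":
        cubes = []
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            next(reader)  # header
            for row in reader:
                fixed = {}
                if row[0]:
                    for pair in row[0].split(";"):
                        n, v = pair.rsplit("=", 1)
                        fixed[n] = int(v)
                free = frozenset(row[1].split(";")) if row[1] else frozenset()
                cubes.append(Cube.make(fixed, free))
        return CubeSet(nodes, cubes)


# ---------------------------------------------------------------------------
# Consistency equations and blocks
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyEquation:
    """Steady-state predicate for one node: [f_i(x) = x_i]."""

    node: str
    expr: Expr
    variables: tuple[str, ...]  # support(f) ∪ {node}, in model node order
    satisfying: frozenset[tuple[int, ...]]  # assignments over `variables`

    @property
    def is_tautology(self) -> bool:
        return len(self.satisfying) == (1 << len(self.variables))

    @property
    def is_contradiction(self) -> bool:
        return not self.satisfying


EQUATION_SUPPORT_GUARD = 20


def consistency_equations(model: BooleanModel) -> list[ConsistencyEquation]:
    order = {n: i for i, n in enumerate(model.nodes)}
    eqs = []
    for node in model.nodes:
        f = model.functions[node].substitute({})  # normalize
        variables = tuple(sorted(f.support() | {node}, key=order.__getitem__))
        if len(variables) > EQUATION_SUPPORT_GUARD:
            raise ValueError(
                f"update rule for {node!r} depends on {len(variables) - 1} "
                f"nodes; supports beyond {EQUATION_SUPPORT_GUARD - 1} are not "
                f"enumerable")
        sat = []
        for bits in product((0, 1), repeat=len(variables)):
            a = dict(zip(variables, bits))
            if f.evaluate(a) == a[node]:
                sat.append(bits)
        eqs.append(ConsistencyEquation(node, f, variables, frozenset(sat)))
    return eqs


@dataclass
class Block:
    """A group of consistency equations with bounded joint support."""

    equations: list[ConsistencyEquation]
    support: tuple[str, ...]


def decompose(model: BooleanModel, budget: int = DEFAULT_BUDGET,
              equations: list[ConsistencyEquation] | None = None) -> list[Block]:
    """Greedily merge equations into blocks of joint support <= budget,
    preferring merges that share the most variables (ties broken by node
    order); deterministic for a fixed model.  Tautological equations
    (free inputs) are dropped — their variables stay unconstrained."""
    if equations is None:
        equations = consistency_equations(model)
    order = {n: i for i, n in enumerate(model.nodes)}
    pending = [e for e in equations if not e.is_tautology]
    for e in pending:
        if len(e.variables) > budget:
            raise ValueError(
                f"equation for {e.node!r} alone has support "
                f"{len(e.variables)} > budget {budget}")
    blocks: list[Block] = []
    pending.sort(key=lambda e: order[e.node])
    while pending:
        current = [pending.pop(0)]
        support = set(current[0].variables)
        while True:
            best = None
            best_key = None
            for i, e in enumerate(pending):
                shared = len(support & set(e.variables))
                if shared == 0:
                    continue
                if len(support | set(e.variables)) > budget:
                    continue
                key = (-shared, order[e.node])
                if best_key is None or key < best_key:
                    best, best_key = i, key
            if best is None:
                break
            e = pending.pop(best)
            current.append(e)
            support |= set(e.variables)
        blocks.append(Block(current, tuple(sorted(support, key=order.__getitem__))))
    return blocks


# ---------------------------------------------------------------------------
# Cube tables and joins
# ---------------------------------------------------------------------------

class _Table:
    """Rows over a fixed variable tuple; cell None means 'either value'.
    Rows are pairwise disjoint as cube sets."""

    __slots__ = ("variables", "rows")

    def __init__(self, variables: tuple[str, ...], rows: list[tuple]):
        self.variables = variables
        self.rows = rows

    def __len__(self):
        return len(self.rows)


def _compact(table: _Table) -> _Table:
    """Merge row pairs differing in exactly one pinned position into a
    single row with that position freed; iterate to a fixed point."""
    rows = set(table.rows)
    n = len(table.variables)
    changed = True
    while changed:
        changed = False
        for pos in range(n):
            buckets: dict[tuple, dict[int | None, tuple]] = {}
            for row in rows:
                key = row[:pos] + row[pos + 1:]
                buckets.setdefault(key, {})[row[pos]] = row
            for key, members in buckets.items():
                if 0 in members and 1 in members:
                    rows.discard(members[0])
                    rows.discard(members[1])
                    rows.add(key[:pos] + (None,) + key[pos:])
                    changed = True
    return _Table(table.variables, sorted(rows, key=_row_key))


def _row_key(row: tuple) -> tuple:
    return tuple(-1 if v is None else v for v in row)


def _equation_table(e: ConsistencyEquation) -> _Table:
    return _compact(_Table(e.variables, sorted(e.satisfying)))


def _solve_block(block: Block, order: dict[str, int],
                 row_cap: int = DEFAULT_ROW_CAP) -> _Table:
    """Joint solutions over the block support: chain hash-joins of the
    member equations' satisfying tables (equivalent to enumerating the
    2^|support| product, but only ever materializes solutions)."""
    table = _equation_table(block.equations[0])
    for e in block.equations[1:]:
        table = _join(table, _equation_table(e), order, row_cap)
        if len(table) == 0:
            return _Table(block.support, [])
    return table


def _join(t1: _Table, t2: _Table, order: dict[str, int],
          row_cap: int) -> _Table:
    variables = tuple(sorted(set(t1.variables) | set(t2.variables),
                             key=order.__getitem__))
    pos1 = {v: i for i, v in enumerate(t1.variables)}
    pos2 = {v: i for i, v in enumerate(t2.variables)}
    shared = [v for v in t1.variables if v in pos2]
    # hash-join on the pinned part of the shared variables; rows with a
    # free (None) shared cell must be matched by scan, so expand them
    # over the shared variables first to keep the join a pure hash join
    t1 = _pin_shared(t1, shared, row_cap)
    t2 = _pin_shared(t2, shared, row_cap)
    pos1 = {v: i for i, v in enumerate(t1.variables)}
    pos2 = {v: i for i, v in enumerate(t2.variables)}
    buckets: dict[tuple, list[tuple]] = {}
    for row in t2.rows:
        buckets.setdefault(tuple(row[pos2[v]] for v in shared), []).append(row)
    out = []
    for row1 in t1.rows:
        key = tuple(row1[pos1[v]] for v in shared)
        for row2 in buckets.get(key, ()):
            merged = []
            for v in variables:
                a = row1[pos1[v]] if v in pos1 else None
                b = row2[pos2[v]] if v in pos2 else None
                merged.append(a if a is not None else b)
            out.append(tuple(merged))
            if len(out) > row_cap:
                raise SolverCapacityError(
                    f"join exceeded {row_cap} rows; raise the cap or use sampling")
    return _compact(_Table(variables, out))


def _pin_shared(t: _Table, shared: list[str], row_cap: int) -> _Table:
    idxs = [t.variables.index(v) for v in shared]
    if not any(row[i] is None for row in t.rows for i in idxs):
        return t
    rows = []
    for row in t.rows:
        free_here = [i for i in idxs if row[i] is None]
        for bits in product((0, 1), repeat=len(free_here)):
            r = list(row)
            for i, b in zip(free_here, bits):
                r[i] = b
            rows.append(tuple(r))
            if len(rows) > row_cap:
                raise SolverCapacityError(
                    f"shared-variable expansion exceeded {row_cap} rows")
    return _Table(t.variables, rows)


def solve(model: BooleanModel, budget: int = DEFAULT_BUDGET,
          row_cap: int = DEFAULT_ROW_CAP) -> CubeSet:
    """All stable states of ``model`` as a disjoint cube set.

    Blocks are solved by bounded enumeration and joined smallest-first
    (pairs sharing variables before variable-disjoint cross products).
    Variables constrained by no equation remain free in every cube.
    """
    order = {n: i for i, n in enumerate(model.nodes)}
    equations = consistency_equations(model)
    if any(e.is_contradiction for e in equations):
        return CubeSet(list(model.nodes), [])
    blocks = decompose(model, budget, equations)
    tables = [_solve_block(b, order, row_cap) for b in blocks]
    if any(len(t) == 0 for t in tables):
        return CubeSet(list(model.nodes), [])

    while len(tables) > 1:
        tables.sort(key=len)
        pair = None
        for i in range(len(tables)):
            for j in range(i + 1, len(tables)):
                if set(tables[i].variables) & set(tables[j].variables):
                    pair = (i, j)
                    break
            if pair:
                break
        if pair is None:
            pair = (0, 1)  # cross product of variable-disjoint systems
        i, j = pair
        t2 = tables.pop(j)
        t1 = tables.pop(i)
        joined = _join(t1, t2, order, row_cap)
        if len(joined) == 0:
            return CubeSet(list(model.nodes), [])
        tables.append(joined)

    constrained = set(tables[0].variables) if tables else set()
    global_free = frozenset(n for n in model.nodes if n not in constrained)
    if not tables:
        return CubeSet(list(model.nodes), [Cube.make({}, global_free)])
    final = tables[0]
    cubes = []
    for row in final.rows:
        fixed = {}
        free = set(global_free)
        for v, val in zip(final.variables, row):
            if val is None:
                free.add(v)
            else:
                fixed[v] = val
        cubes.append(Cube.make(fixed, free))
    return CubeSet(list(model.nodes), cubes)


def brute_force_fixed_points(model: BooleanModel) -> CubeSet:
    """Oracle: test all 2^n states directly (guarded at n <= 22)."""
    n = model.n_nodes
    if n > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"brute force refused for n={n} > {BRUTE_FORCE_GUARD}; use solve()")
    cubes = []
    for bits in product((0, 1), repeat=n):
        s = dict(zip(model.nodes, bits))
        if model.step(s) == s:
            cubes.append(Cube.make(s, frozenset()))
    return CubeSet(list(model.nodes), cubes)
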