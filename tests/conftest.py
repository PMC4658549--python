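"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from logicnet import (BooleanModel, NetworkSpec, SignedEdge, SignedNetwork,
                      build_model, make_network)
from logicnet.expr import And, Const, Expr, Not, Or, Var


def canon_states(fps):
    """Stable-state set as a sorted list of value tuples (for set equality)."""
    return sorted(tuple(s[n] for n in fps.nodes) for s in fps.expand())


def random_network(seed: int, n_max: int = 12) -> SignedNetwork:
    """Small random signed network, deterministic in seed."""
    r = random.Random(seed)
    return make_network(NetworkSpec(
        n_nodes=r.randint(3, n_max),
        mean_in_degree=r.uniform(1.0, 2.2),
        p_inh=r.uniform(0.0, 0.6),
        p_and=r.uniform(0.0, 0.4),
        n_inputs=r.randint(0, 2),
        seed=seed,
    ))


def random_expr(rng: random.Random, variables: list[str], depth: int = 3) -> Expr:
    """Random expression tree over the given variables."""
    if depth == 0 or rng.random() < 0.3:
        if rng.random() < 0.1:
            return Const(rng.randint(0, 1))
        return Var(rng.choice(variables))
    op = rng.choice(["and", "or", "not"])
    if op == "not":
        return Not.of(random_expr(rng, variables, depth - 1))
    k = rng.randint(2, 3)
    children = [random_expr(rng, variables, depth - 1) for _ in range(k)]
    return (And if op == "and" else Or).of(*children)


def random_rule_model(seed: int, n_max: int = 10) -> BooleanModel:
    """Random explicit-rule model (not derived from a network)."""
    r = random.Random(seed)
    n = r.randint(2, n_max)
    nodes = [f"x{i}" for i in range(n)]
    funcs = {}
    for node in nodes:
        support = r.sample(nodes, k=min(n, r.randint(1, 3)))
        funcs[node] = random_expr(r, support, depth=2)
    return BooleanModel(nodes, funcs)


def brute_force_loops(net: SignedNetwork):
    """Independent DFS enumeration of simple signed cycles.

    Each cycle is counted once up to rotation (canonical start = smallest
    node) and once per choice among parallel edges.  Returns a sorted
    list of (node_tuple, sign_tuple).
    """
    adj: dict[str, list[tuple[str, int]]] = {n: [] for n in net.nodes}
    for e in net.edges:
        adj[e.source].append((e.target, e.sign))
    found = []
    order = sorted(net.nodes)
    rank = {n: i for i, n in enumerate(order)}

    def dfs(start, node, path, signs):
        for nxt, sign in adj[node]:
            if nxt == start:
                found.append((tuple(path), tuple(signs) + (sign,)))
            elif rank[nxt] > rank[start] and nxt not in path:
                dfs(start, nxt, path + [nxt], signs + [sign])

    for start in order:
        dfs(start, start, [start], [])
    return sorted(found)


@pytest.fixture
def toy_negative_loop() -> BooleanModel:
    """f_A = !C, f_B = A, f_C = B: a 3-node negative loop, no fixed point."""
    return BooleanModel(
        ["A", "B", "C"],
        {"A": Not.of(Var("C")), "B": Var("A"), "C": Var("B")})


@pytest.fixture
def mutual_activation() -> BooleanModel:
    """A <-> B activation: fixed points 00 and 11."""
    net = SignedNetwork(["A", "B"],
                        [SignedEdge("A", "B", 1), SignedEdge("B", "A", 1)])
    return build_model(net)


@pytest.fixture
def chain_model() -> BooleanModel:
    """Activation chain A -> B -> C under the default convention."""
    net = SignedNetwork(["A", "B", "C"],
                        [SignedEdge("A", "B", 1), SignedEdge("B", "C", 1)])
    return build_model(net)
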