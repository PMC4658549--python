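"""Boolean models: per-node update rules and synchronous dynamics.

A model assigns every node one update expression; the synchronous map
updates all nodes simultaneously.  Models come either from explicit rule
files or from a signed network under a stated rule convention.  The
default convention is *inhibitor-dominant*: a node turns ON when at
least one of its activator terms is ON and none of its inhibitor terms
is — the de-facto standard for literature-curated logical models.
Network inputs (no regulators) get the identity rule ``f = x`` and so
stay free in every stable state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .expr import And, Const, Expr, Not, Or, Var, exprs_equivalent
from .network import SignedNetwork

__all__ = ["BooleanModel", "build_model", "ModelValidationError", "CONVENTIONS"]


class ModelValidationError(ValueError):
    pass


@dataclass
class BooleanModel:
    """Ordered node list plus one update function per node."""

    nodes: list[str]
    functions: dict[str, Expr] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ModelValidationError("duplicate node names")
        node_set = set(self.nodes)
        missing = node_set - set(self.functions)
        if missing:
            raise ModelValidationError(f"nodes without update rules: {sorted(missing)}")
        extra = set(self.functions) - node_set
        if extra:
            raise ModelValidationError(f"rules for undeclared nodes: {sorted(extra)}")
        for node, f in self.functions.items():
            undeclared = f.support() - node_set
            if undeclared:
                raise ModelValidationError(
                    f"rule for {node!r} references undeclared {sorted(undeclared)}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def evaluate(self, node: str, state: dict[str, int]) -> int:
        return self.functions[node].evaluate(state)

    def step(self, state: dict[str, int]) -> dict[str, int]:
        """One synchronous update: every node reads the same input state."""
        missing = set(self.nodes) - set(state)
        if missing:
            raise KeyError(f"state is missing nodes {sorted(missing)}")
        return {n: self.functions[n].evaluate(state) for n in self.nodes}

    def is_fixed_point(self, state: dict[str, int]) -> bool:
        return self.step(state) == state

    def clamp(self, node: str, value: int) -> "BooleanModel":
        """Pin ``node`` to ``value``: its rule becomes the constant and the
        constant is folded through every other rule.  Folding never
        enlarges a support."""
        if node not in self.functions:
            raise KeyError(f"unknown node {node!r}")
        new_funcs = {
            n: (Const(value) if n == node else f.substitute({node: value}))
            for n, f in self.functions.items()
        }
        return BooleanModel(list(self.nodes), new_funcs)

    def free_input_nodes(self) -> list[str]:
        """Nodes with the identity rule f = x (unconstrained inputs)."""
        return [n for n in self.nodes if self.functions[n] == Var(n)]

    def equivalent_to(self, other: "BooleanModel") -> bool:
        """Same node set and node-by-node equal truth tables."""
        if set(self.nodes) != set(other.nodes):
            return False
        return all(
            exprs_equivalent(self.functions[n], other.functions[n])
            for n in self.nodes
        )


def _inhibitor_dominant(net: SignedNetwork, target: str) -> Expr:
    edges = net.regulators_of(target)
    if not edges:
        return Var(target)  # network input: free variable
    act_groups: dict[str | None, list[str]] = {}
    inh_groups: dict[str | None, list[str]] = {}
    for i, e in enumerate(edges):
        groups = act_groups if e.sign == 1 else inh_groups
        key = e.and_group if e.and_group is not None else f"__solo_{i}"
        groups.setdefault(key, []).append(e.source)
    act_terms = [And.of(*(Var(s) for s in sources)) for sources in act_groups.values()]
    inh_terms = [And.of(*(Var(s) for s in sources)) for sources in inh_groups.values()]
    if act_terms and inh_terms:
        return And.of(Or.of(*act_terms), *(Not.of(t) for t in inh_terms))
    if act_terms:
        return Or.of(*act_terms)
    return And.of(*(Not.of(t) for t in inh_terms))


CONVENTIONS = {"inhibitor-dominant": _inhibitor_dominant}


def build_model(net: SignedNetwork, convention: str = "inhibitor-dominant") -> BooleanModel:
    """Derive a Boolean model from a signed network.

    ``inhibitor-dominant``: f_target = (OR over activator terms) AND
    (AND over negated inhibitor terms); edges sharing an AND-group tag
    form a single conjunctive term; a node with only activators omits
    the inhibitor clause, only inhibitors gives the pure AND of
    negations, and a regulator-free node gets f = x.
    """
    try:
        rule = CONVENTIONS[convention]
    except KeyError:
        raise ModelValidationError(
            f"unknown rule convention {convention!r}; "
            f"available: {sorted(CONVENTIONS)}") from None
    return BooleanModel(
        list(net.nodes), {n: rule(net, n) for n in net.nodes})
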