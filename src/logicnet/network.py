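"""Signed interaction networks.

A :class:`SignedNetwork` is a directed graph of genes whose edges are
activating (+1) or inhibiting (-1).  Edges may carry an AND-group tag:
edges sharing a tag on the same target jointly gate that target (all of
them must be ON for the combined term to fire), mirroring the AND
connectors of curated signalling maps.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["SignedEdge", "SignedNetwork", "ExpressionAnnotation", "NetworkValidationError"]


class NetworkValidationError(ValueError):
    """Structural problem in a signed network."""


@dataclass(frozen=True)
class SignedEdge:
    """One signed interaction: ``source`` activates (+1) or inhibits (-1)
    ``target``; ``and_group`` tags edges that jointly gate the target."""

    source: str
    target: str
    sign: int
    and_group: str | None = None

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise NetworkValidationError(
                f"edge sign must be +1 or -1, got {self.sign!r}")
        if not self.source or not self.target:
            raise NetworkValidationError("edge endpoints must be non-empty")


@dataclass
class SignedNetwork:
    """Ordered node list plus signed edges.

    Invariants enforced on construction: unique nodes, every edge endpoint
    declared, no duplicate (source, target, sign) triples, and every
    AND-group shared by at least two edges on the same target.  Self-loops
    and antiparallel duplicate pairs (same endpoints, opposite signs) are
    legal — both occur in curated logical models.
    """

    nodes: list[str]
    edges: list[SignedEdge] = field(default_factory=list)

    def __post_init__(self):
        dupes = [n for n, c in Counter(self.nodes).items() if c > 1]
        if dupes:
            raise NetworkValidationError(f"duplicate nodes: {dupes}")
        node_set = set(self.nodes)
        seen: set[tuple[str, str, int]] = set()
        group_members: dict[tuple[str, str | None], int] = defaultdict(int)
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in node_set:
                    raise NetworkValidationError(
                        f"edge endpoint {endpoint!r} not in node list")
            key = (e.source, e.target, e.sign)
            if key in seen:
                raise NetworkValidationError(f"duplicate edge {key}")
            seen.add(key)
            if e.and_group is not None:
                group_members[(e.target, e.and_group)] += 1
        singletons = [g for g, c in group_members.items() if c < 2]
        if singletons:
            raise NetworkValidationError(
                f"AND-groups need >= 2 member edges on their target; "
                f"singletons: {singletons}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def regulators_of(self, target: str) -> list[SignedEdge]:
        return [e for e in self.edges if e.target == target]

    def input_nodes(self) -> list[str]:
        """Nodes with no incoming edge (the network's free inputs)."""
        targets = {e.target for e in self.edges}
        return [n for n in self.nodes if n not in targets]

    def __eq__(self, other):
        """Semantic equality: same node set and edge set.  Node order is a
        presentation detail (readers use first-appearance order, writers
        sort), so it does not participate in equality."""
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and set(self.edges) == set(other.edges)


class ExpressionAnnotation(dict):
    """gene -> expected steady expression level (0, 1 or None=unknown)."""

    def __init__(self, levels: Mapping[str, int | None] = ()):
        super().__init__()
        for gene, level in dict(levels).items():
            self[gene] = level

    def __setitem__(self, gene: str, level: int | None):
        if level not in (0, 1, None):
            raise ValueError(
                f"expected level for {gene!r} must be 0, 1 or None, got {level!r}")
        super().__setitem__(gene, level)

    def known(self) -> dict[str, int]:
        return {g: v for g, v in self.items() if v is not None}

    def check_subset(self, nodes: Iterable[str]) -> list[str]:
        """Genes annotated but absent from ``nodes`` (callers warn/skip)."""
        node_set = set(nodes)
        return [g for g in self if g not in node_set]
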