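"""Structural analysis of signed networks.

Feedback loops are simple directed cycles signed by inhibition parity:
a loop is negative exactly when it carries an odd number of inhibiting
edges.  Node-level cycles come from :func:`networkx.simple_cycles`; a
node cycle with antiparallel duplicate edges (same source/target, both
signs) expands into one loop per sign combination.  Self-loops count as
length-1 cycles signed by their single edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import networkx as nx
import pandas as pd

from .network import SignedNetwork

__all__ = [
    "FeedbackLoop", "LoopCensus", "LoopOverflowError",
    "strongly_connected_components", "enumerate_loops", "participation_table",
]

DEFAULT_LOOP_CAP = 1_000_000


class LoopOverflowError(RuntimeError):
    """Raised when the loop census exceeds the safety cap; set max_length."""


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle (canonical rotation: lexicographically
    smallest node first) with its parity sign."""

    nodes: tuple[str, ...]
    signs: tuple[int, ...]  # edge signs along the cycle, aligned with nodes

    @property
    def sign(self) -> int:
        n_inhib = sum(1 for s in self.signs if s == -1)
        return -1 if n_inhib % 2 else 1

    @property
    def length(self) -> int:
        return len(self.nodes)

    def __str__(self):
        return ">".join(self.nodes)


def _canonical_rotation(nodes: tuple[str, ...], signs: tuple[int, ...]):
    k = nodes.index(min(nodes))
    return nodes[k:] + nodes[:k], signs[k:] + signs[:k]


@dataclass
class LoopCensus:
    """All feedback loops plus per-node participation counts."""

    loops: list[FeedbackLoop]
    nodes: list[str]
    counts_all: dict[str, int] = field(init=False)
    counts_negative: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.counts_all = {n: 0 for n in self.nodes}
        self.counts_negative = {n: 0 for n in self.nodes}
        for loop in self.loops:
            neg = loop.sign == -1
            for n in set(loop.nodes):
                self.counts_all[n] += 1
                if neg:
                    self.counts_negative[n] += 1

    @property
    def n_loops(self) -> int:
        return len(self.loops)

    @property
    def n_negative(self) -> int:
        return sum(1 for l in self.loops if l.sign == -1)

    @property
    def n_positive(self) -> int:
        return self.n_loops - self.n_negative

    def without_self_loops(self) -> "LoopCensus":
        return LoopCensus([l for l in self.loops if l.length > 1], self.nodes)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"cycle": [str(l) for l in self.loops],
             "length": [l.length for l in self.loops],
             "sign": [l.sign for l in self.loops]})
        df.to_csv(path, index=False)


def _as_digraph(net: SignedNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for e in net.edges:
        if g.has_edge(e.source, e.target):
            g[e.source][e.target]["signs"] = tuple(
                sorted(set(g[e.source][e.target]["signs"]) | {e.sign}, reverse=True))
        else:
            g.add_edge(e.source, e.target, signs=(e.sign,))
    return g


def strongly_connected_components(net: SignedNetwork) -> list[frozenset[str]]:
    """Maximal SCCs, largest first; ties broken by smallest member name."""
    comps = [frozenset(c) for c in nx.strongly_connected_components(_as_digraph(net))]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def enumerate_loops(net: SignedNetwork,
                    max_length: int | None = None,
                    cap: int = DEFAULT_LOOP_CAP) -> LoopCensus:
    """Census of all simple directed cycles, each counted once up to
    rotation and once per combination of parallel-edge signs.

    Raises :class:`LoopOverflowError` beyond ``cap`` loops; pass
    ``max_length`` to restrict cycle length on dense networks.
    """
    g = _as_digraph(net)
    loops: list[FeedbackLoop] = []
    for cycle in nx.simple_cycles(g, length_bound=max_length):
        sign_options = [
            g[cycle[i]][cycle[(i + 1) % len(cycle)]]["signs"]
            for i in range(len(cycle))
        ]
        for signs in product(*sign_options):
            nodes_c, signs_c = _canonical_rotation(tuple(cycle), tuple(signs))
            loops.append(FeedbackLoop(nodes_c, signs_c))
            if len(loops) > cap:
                raise LoopOverflowError(
                    f"more than {cap} loops; pass max_length to bound the census")
    loops.sort(key=lambda l: (l.length, l.nodes, l.signs))
    return LoopCensus(loops, list(net.nodes))


def participation_table(census: LoopCensus) -> pd.DataFrame:
    """Per-node loop participation, sorted by overall fraction descending.

    Columns: node, n_loops, frac_loops, n_negative, frac_negative.
    Fractions are 0 when the census has no loops of that kind.
    """
    total, total_neg = census.n_loops, census.n_negative
    rows = []
    for n in census.nodes:
        c, cn = census.counts_all[n], census.counts_negative[n]
        rows.append({
            "node": n,
            "n_loops": c,
            "frac_loops": c / total if total else 0.0,
            "n_negative": cn,
            "frac_negative": cn / total_neg if total_neg else 0.0,
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["frac_loops", "node"],
                          ascending=[False, True]).reset_index(drop=True)
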