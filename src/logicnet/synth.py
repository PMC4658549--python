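"""Synthetic generators: every pipeline stage testable without downloads.

Three generators, all pure functions of their seed:

* :func:`make_network` — random signed digraphs shaped like curated
  signalling maps (default shape: 91 nodes, mean in-degree 2 giving
  ~182 edges, a designated set of regulator-free inputs, a tunable
  inhibition fraction and AND-connector frequency).
* :func:`make_clustered_states` — planted-cluster binary matrices
  (random centroids plus independent bit flips) with ground-truth labels
  for clustering-recovery experiments.
* :func:`make_expression` — noisy continuous expression matrices whose
  samples are stable states of a model mapped to low/high levels plus
  Gaussian noise, the desk-scale stand-in for public microarray sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixedpoints import CubeSet
from .model import BooleanModel
from .network import SignedEdge, SignedNetwork

__all__ = ["NetworkSpec", "ExpressionSpec", "make_network",
           "make_clustered_states", "make_expression"]


@dataclass(frozen=True)
class NetworkSpec:
    """Shape parameters for a random signed digraph.

    Defaults emulate a literature-curated cancer signalling map:
    91 nodes with mean in-degree 2 (about 182 interactions), roughly a
    third of them inhibitory, occasional AND connectors, and 20
    regulator-free inputs so the model keeps free dimensions.
    """

    n_nodes: int = 91
    mean_in_degree: float = 2.0
    p_inh: float = 0.3
    p_and: float = 0.1
    n_inputs: int = 20
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_inh <= 1 and 0 <= self.p_and <= 1):
            raise ValueError("p_inh and p_and must lie in [0, 1]")
        if self.n_inputs >= self.n_nodes:
            raise ValueError("n_inputs must be < n_nodes")
        if self.mean_in_degree > self.n_nodes - 1:
            raise ValueError("mean in-degree cannot exceed n-1")
        if self.mean_in_degree <= 0:
            raise ValueError("mean in-degree must be positive")


@dataclass(frozen=True)
class ExpressionSpec:
    """Two-level Gaussian expression model: OFF -> mu0, ON -> mu1, plus
    N(0, sigma) noise.  Default sigma is 10% of the level separation."""

    n_samples: int = 30
    mu0: float = 2.0
    mu1: float = 8.0
    sigma: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.mu1 <= self.mu0:
            raise ValueError("mu1 must exceed mu0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def make_network(spec: NetworkSpec) -> SignedNetwork:
    """Random signed digraph per ``spec``.

    ``mean_in_degree`` is the network-wide mean, so the expected edge
    count is ``n_nodes * mean_in_degree`` (the default shape gives
    ~182 edges on 91 nodes).  The first ``n_inputs`` nodes (g001..)
    receive no regulators; every other node draws ``1 + Poisson(lam)``
    distinct regulators uniformly, with ``lam`` set so the network-wide
    mean comes out right and no regulated node is left orphaned.  Each
    edge is inhibitory with probability ``p_inh``.  With probability
    ``p_and`` a node with >= 2 activators has two of them tagged into
    one AND group.  Same seed, same network — byte-identical on disk.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_nodes))
    nodes = [f"g{i + 1:0{width}d}" for i in range(spec.n_nodes)]
    inputs = set(nodes[:spec.n_inputs])
    n_regulated = spec.n_nodes - spec.n_inputs
    lam = max(spec.n_nodes * spec.mean_in_degree / n_regulated - 1, 0.0)
    edges: list[SignedEdge] = []
    for target in nodes:
        if target in inputs:
            continue
        k = 1 + rng.poisson(lam)
        k = min(k, spec.n_nodes - 1)
        candidates = [n for n in nodes if n != target]
        sources = rng.choice(candidates, size=k, replace=False)
        signs = np.where(rng.random(k) < spec.p_inh, -1, 1)
        group: dict[str, str | None] = {s: None for s in sources}
        activators = [s for s, sg in zip(sources, signs) if sg == 1]
        if len(activators) >= 2 and rng.random() < spec.p_and:
            pair = rng.choice(activators, size=2, replace=False)
            for s in pair:
                group[s] = "and1"
        for s, sg in zip(sources, signs):
            edges.append(SignedEdge(str(s), target, int(sg), group[str(s)]))
    return SignedNetwork(nodes, edges)


def make_clustered_states(n_states: int, n_nodes: int, k: int,
                          flip_prob: float, seed: int = 0):
    """Planted-cluster binary matrix: k random centroids, each state a
    centroid copy with independent bit flips.  Returns
    ``(matrix, labels)`` with the ground-truth cluster labels."""
    if k > n_states:
        raise ValueError("k cannot exceed n_states")
    if not 0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    centroids = rng.integers(0, 2, size=(k, n_nodes))
    labels = np.sort(rng.integers(0, k, size=n_states))
    labels[:k] = np.arange(k)  # every cluster non-empty
    labels = np.sort(labels)
    states = centroids[labels]
    flips = rng.random(states.shape) < flip_prob
    return np.where(flips, 1 - states, states).astype(np.int8), labels


def make_expression(model: BooleanModel, fps: CubeSet,
                    spec: ExpressionSpec) -> "pd.DataFrame":
    """Sample x gene expression matrix: each sample is a stable state
    drawn uniformly (with replacement across draws, without within the
    cube sampler) mapped {0 -> mu0, 1 -> mu1} plus Gaussian noise."""
    import pandas as pd

    if fps.cardinality == 0:
        raise ValueError("model has no stable states to emulate")
    rng = np.random.default_rng(spec.seed)
    n_distinct = min(spec.n_samples, fps.cardinality)
    pool = fps.sample_states(n_distinct, seed=int(rng.integers(2**31)))
    picks = rng.integers(0, n_distinct, size=spec.n_samples)
    rows = []
    for p in picks:
        s = pool[p]
        level = np.array([spec.mu1 if s[n] else spec.mu0 for n in fps.nodes])
        rows.append(level + rng.normal(0.0, spec.sigma, size=len(fps.nodes)))
    return pd.DataFrame(rows, columns=fps.nodes,
                        index=[f"sample{i + 1}" for i in range(spec.n_samples)])
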