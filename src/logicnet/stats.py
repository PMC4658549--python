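"""Statistics over the stable-state set.

The analysis mirrors how stable states of a large logical model are
summarized: per-node expression rates (the fraction of stable states in
which a node is ON), standardization and k-means clustering of an
explicit or sampled state matrix into phenotype clusters, agglomerative
merging of clusters into two groups, Table-style per-group rate
differences/ratios with selection flags, and a consistency score of the
model against known ON/OFF expression annotations.

Rates over the full set are computed cube-analytically (exact, no
expansion); cluster and group rates are computed on the clustered state
matrix, which is the full expansion when small enough and a seeded
uniform sample otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .fixedpoints import CubeSet
from .network import ExpressionAnnotation

__all__ = [
    "ClusterSummary", "rate_of_one", "nonconstant_nodes", "standardize",
    "states_matrix", "kmeans_cluster", "merge_to_groups", "group_rate_table",
    "model_consistency",
]

logger = logging.getLogger(__name__)

DEFAULT_EXPANSION_CAP = 1 << 21
RATIO_HIGH, RATIO_LOW = 1.2, 0.8
DIFFERENCE_CUT = 0.5


def rate_of_one(fps: CubeSet) -> dict[str, float]:
    """Exact per-node rate of '1' over all stable states, cube-analytic:
    a pinned node contributes value x 2^|free|, a free node 2^(|free|-1)."""
    total = fps.cardinality
    if total == 0:
        raise ValueError("rate undefined: empty stable-state set")
    return {n: fps.ones_count(n) / total for n in fps.nodes}


def nonconstant_nodes(fps: CubeSet) -> list[str]:
    """Nodes that are neither always 0 nor always 1 across stable states."""
    total = fps.cardinality
    if total == 0:
        raise ValueError("empty stable-state set")
    return [n for n in fps.nodes if 0 < fps.ones_count(n) < total]


def standardize(states: np.ndarray, columns: list[str]):
    """Center each column to mean 0 / sd 1; constant columns carry no
    clustering information and are dropped (logged).

    Returns ``(Z, kept_columns)``.
    """
    states = np.asarray(states, dtype=float)
    if states.shape[0] < 2:
        raise ValueError("need >= 2 rows to standardize")
    mean = states.mean(axis=0)
    sd = states.std(axis=0)  # population sd, ddof=0
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns constant: nothing to cluster")
    dropped = [c for c, k in zip(columns, keep) if not k]
    if dropped:
        logger.info("dropped %d constant columns: %s", len(dropped), dropped)
    z = (states[:, keep] - mean[keep]) / sd[keep]
    return z, [c for c, k in zip(columns, keep) if k]


def states_matrix(fps: CubeSet, cap: int = DEFAULT_EXPANSION_CAP,
                  seed: int = 0) -> np.ndarray:
    """0/1 matrix of stable states: the full expansion when the set has
    at most ``cap`` states, else a seeded uniform sample of ``cap``."""
    if fps.cardinality <= cap:
        rows = list(fps.expand())
    else:
        logger.info("sampling %d of %d stable states", cap, fps.cardinality)
        rows = fps.sample_states(cap, seed)
    return np.array([[s[n] for n in fps.nodes] for s in rows], dtype=np.int8)


@dataclass
class ClusterSummary:
    """k-means result on (standardized) stable states, plus the optional
    two-group merge.  Cluster labels are 0..k-1 in size-descending order."""

    labels: np.ndarray
    sizes: list[int]
    centroids: np.ndarray          # standardized space, one row per cluster
    columns: list[str]             # columns the centroids live in
    group_of: dict[int, int] = field(default_factory=dict)  # cluster -> group

    @property
    def k(self) -> int:
        return len(self.sizes)

    def group_labels(self) -> np.ndarray:
        if not self.group_of:
            raise ValueError("no group merge computed; call merge_to_groups")
        return np.array([self.group_of[c] for c in self.labels])


def kmeans_cluster(states: np.ndarray, columns: list[str], k: int = 4,
                   seed: int = 0, restarts: int = 10) -> ClusterSummary:
    """Standardize, then Lloyd k-means (Euclidean, k-means++ seeding,
    best of ``restarts`` initializations).  Deterministic given ``seed``
    and invariant to row order.  Labels are renumbered so cluster 0 is
    the largest."""
    states = np.asarray(states)
    if states.shape[0] < k:
        raise ValueError(f"{states.shape[0]} rows < k={k}")
    z, kept = standardize(states, columns)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed,
                algorithm="lloyd")
    raw = km.fit_predict(z)
    counts = np.bincount(raw, minlength=k)
    if (counts == 0).any():
        raise RuntimeError("k-means produced an empty cluster; lower k")
    # stable size-descending relabeling (ties by old label)
    new_order = sorted(range(k), key=lambda c: (-counts[c], c))
    relabel = {old: new for new, old in enumerate(new_order)}
    labels = np.array([relabel[c] for c in raw])
    centroids = km.cluster_centers_[new_order]
    return ClusterSummary(labels=labels,
                          sizes=[int(counts[c]) for c in new_order],
                          centroids=centroids, columns=kept)


def merge_to_groups(summary: ClusterSummary, n_groups: int = 2) -> dict[int, int]:
    """Agglomeratively merge cluster centroids (Euclidean, complete
    linkage) down to ``n_groups``; fills and returns ``summary.group_of``
    with groups numbered 0..n_groups-1 by smallest member cluster."""
    k = summary.k
    if k < n_groups:
        raise ValueError(f"k={k} < n_groups={n_groups}")
    if k == n_groups:
        mapping = {c: c for c in range(k)}
    else:
        lk = linkage(summary.centroids, method="complete", metric="euclidean")
        flat = fcluster(lk, t=n_groups, criterion="maxclust")
        first_seen: dict[int, int] = {}
        mapping = {}
        for c, g in enumerate(flat):
            mapping[c] = first_seen.setdefault(g, len(first_seen))
    summary.group_of = mapping
    return mapping


def group_rate_table(states: np.ndarray, columns: list[str],
                     summary: ClusterSummary,
                     marker: str | None = None) -> pd.DataFrame:
    """Per-node rates of '1' per cluster and per group, with the group
    difference/ratio columns and the selection flags.

    Group numbering: when ``marker`` is given, group 1 is the group with
    the higher marker rate; otherwise group 1 is the group with the
    smaller total mass.  A gene is 'selected' when |difference| > 0.5 or
    its ratio falls outside [0.8, 1.2]; a zero group-2 rate makes the
    ratio infinite (flagged, not an error).
    """
    states = np.asarray(states, dtype=float)
    glabels = summary.group_labels()
    groups = sorted(set(summary.group_of.values()))
    if len(groups) != 2:
        raise ValueError("rate table needs exactly 2 groups")
    g_rates = {g: states[glabels == g].mean(axis=0) for g in groups}
    if marker is not None:
        if marker not in columns:
            raise KeyError(f"marker {marker!r} not among columns")
        mi = columns.index(marker)
        order = sorted(groups, key=lambda g: -g_rates[g][mi])
    else:
        masses = {g: int((glabels == g).sum()) for g in groups}
        order = sorted(groups, key=lambda g: (masses[g], g))
    g1, g2 = order
    rows = []
    for j, node in enumerate(columns):
        overall = states[:, j].mean()
        per_cluster = {
            f"cluster{c + 1}": states[summary.labels == c, j].mean()
            for c in range(summary.k)
        }
        r1, r2 = g_rates[g1][j], g_rates[g2][j]
        diff = r1 - r2
        ratio = np.inf if r2 == 0 else r1 / r2
        selected = abs(diff) > DIFFERENCE_CUT or ratio > RATIO_HIGH or ratio < RATIO_LOW
        rows.append({"node": node, "all": overall, **per_cluster,
                     "group1": r1, "group2": r2, "difference": diff,
                     "ratio": ratio, "selected": bool(selected)})
    df = pd.DataFrame(rows)
    df.attrs["group1_clusters"] = sorted(
        c for c, g in summary.group_of.items() if g == g1)
    df.attrs["group2_clusters"] = sorted(
        c for c, g in summary.group_of.items() if g == g2)
    return df


def model_consistency(fps: CubeSet, annot: ExpressionAnnotation):
    """Fraction of annotated genes whose overall rate of '1' falls on the
    expected side (> 0.5 for expected ON, < 0.5 for expected OFF; a rate
    of exactly 0.5 is inconclusive and excluded, as are unknown levels
    and genes absent from the model).

    Returns ``(fraction, per_gene_table)``; the fraction is ``nan`` when
    nothing is evaluable.
    """
    if not annot:
        raise ValueError("empty annotation")
    missing = annot.check_subset(fps.nodes)
    if missing:
        logger.warning("annotation genes absent from model, skipped: %s", missing)
    rates = rate_of_one(fps)
    rows = []
    n_consistent = n_evaluable = 0
    for gene, expected in annot.items():
        if gene in missing:
            rows.append({"gene": gene, "expected": expected,
                         "rate": np.nan, "status": "absent"})
            continue
        rate = rates[gene]
        if expected is None:
            status = "unknown"
        elif rate == 0.5:
            status = "inconclusive"
        else:
            ok = rate > 0.5 if expected == 1 else rate < 0.5
            status = "consistent" if ok else "inconsistent"
            n_evaluable += 1
            n_consistent += int(ok)
        rows.append({"gene": gene, "expected": expected,
                     "rate": rate, "status": status})
    fraction = n_consistent / n_evaluable if n_evaluable else float("nan")
    return fraction, pd.DataFrame(rows)
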