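"""Clamp-and-propagate control effects.

Clamping a node (knockout = 0, overexpression = 1) and repeatedly
constant-folding every update rule yields the set of nodes *forced* to a
constant by the perturbation.  For controlling node k the four sets are

* ``A0`` / ``A1``: nodes forced to 0 / 1 after clamping k := 0,
* ``B0`` / ``B1``: nodes forced to 0 / 1 after clamping k := 1.

Propagation is sound but deliberately incomplete: it reports guaranteed
constants only; rules that merely simplify without becoming constant are
*partial* effects, counted in a side report and excluded from the
effect matrix.  The per-pair effect code summarizes the four sets:

====  =======================================================
code  meaning for pair (i controlling, j controlled)
====  =======================================================
 3    j in A(i,0) ∩ B(i,1)   — co-expressed with i
-3    j in A(i,1) ∩ B(i,0)   — oppositely co-expressed
 2    j in B(i,1) only       — i ON forces j ON
-2    j in B(i,0) only       — i ON forces j OFF
 1    j in A(i,0) only       — i OFF forces j OFF
-1    j in A(i,1) only       — i OFF forces j ON
 5    j forced to the same constant under both clamps (unclear)
 0    no (complete) effect
====  =======================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .expr import Const
from .model import BooleanModel

__all__ = [
    "ControlSets", "EffectMatrix", "propagate", "control_sets",
    "effect_matrix", "consistency_rate", "multi_dataset_consistency",
]

logger = logging.getLogger(__name__)

EFFECT_CODES = (-3, -2, -1, 0, 1, 2, 3, 5)


def propagate(model: BooleanModel, node: str, value: int):
    """Forced-constant sets after clamping ``node`` := ``value``.

    Iteratively substitutes every known constant into every remaining
    rule; a rule that folds to a constant adds its node.  The constant
    map grows monotonically, so at most n sweeps run.  Returns
    ``(forced_to_0, forced_to_1, n_partial)`` with the clamped node
    excluded; ``n_partial`` counts rules whose support shrank without
    becoming constant (partial effects).
    """
    constants = {node: value}
    funcs = {n: f for n, f in model.functions.items() if n != node}
    original_support = {n: len(f.support()) for n, f in funcs.items()}
    while True:
        grew = False
        for n in list(funcs):
            folded = funcs[n].substitute(constants)
            funcs[n] = folded
            if isinstance(folded, Const) and n not in constants:
                constants[n] = folded.value
                grew = True
        if not grew:
            break
    forced0 = frozenset(n for n, v in constants.items() if n != node and v == 0)
    forced1 = frozenset(n for n, v in constants.items() if n != node and v == 1)
    n_partial = sum(
        1 for n, f in funcs.items()
        if n not in constants and len(f.support()) < original_support[n])
    return forced0, forced1, n_partial


@dataclass(frozen=True)
class ControlSets:
    """The four forced sets for one controlling node."""

    node: str
    A0: frozenset[str]  # clamp 0 -> forced to 0
    A1: frozenset[str]  # clamp 0 -> forced to 1
    B0: frozenset[str]  # clamp 1 -> forced to 0
    B1: frozenset[str]  # clamp 1 -> forced to 1
    n_partial_off: int = 0
    n_partial_on: int = 0

    def __post_init__(self):
        if self.A0 & self.A1 or self.B0 & self.B1:
            raise ValueError(
                f"{self.node}: a node forced to both 0 and 1 under one clamp")

    def code_for(self, j: str) -> int:
        in_a0, in_a1 = j in self.A0, j in self.A1
        in_b0, in_b1 = j in self.B0, j in self.B1
        if in_a0 and in_b1:
            return 3
        if in_a1 and in_b0:
            return -3
        if (in_a0 and in_b0) or (in_a1 and in_b1):
            return 5  # same constant whichever way k is clamped
        if in_a0:
            return 1
        if in_a1:
            return -1
        if in_b1:
            return 2
        if in_b0:
            return -2
        return 0


def control_sets(model: BooleanModel) -> dict[str, ControlSets]:
    """Propagate both clamp values for every node."""
    out = {}
    for node in model.nodes:
        a0, a1, p_off = propagate(model, node, 0)
        b0, b1, p_on = propagate(model, node, 1)
        out[node] = ControlSets(node, A0=a0, A1=a1, B0=b0, B1=b1,
                                n_partial_off=p_off, n_partial_on=p_on)
    return out


@dataclass
class EffectMatrix:
    """node x node integer effect codes; rows control, columns are
    controlled; the diagonal is fixed at 0."""

    nodes: list[str]
    codes: np.ndarray = field(default=None)

    def code(self, i: str, j: str) -> int:
        return int(self.codes[self.nodes.index(i), self.nodes.index(j)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.nodes, columns=self.nodes)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @staticmethod
    def from_csv(path) -> "EffectMatrix":
        df = pd.read_csv(path, index_col=0)
        return EffectMatrix(list(df.index), df.to_numpy(dtype=int))


def effect_matrix(cs: dict[str, ControlSets]) -> EffectMatrix:
    nodes = list(cs)
    codes = np.zeros((len(nodes), len(nodes)), dtype=int)
    for a, i in enumerate(nodes):
        sets = cs[i]
        for b, j in enumerate(nodes):
            if i != j:
                codes[a, b] = sets.code_for(j)
    return EffectMatrix(nodes, codes)


def _split_high_low(values: np.ndarray):
    """Median split; ties go to 'low'."""
    med = float(np.median(values))
    high = values > med
    return high, ~high


def consistency_rate(effects: EffectMatrix, expr: pd.DataFrame,
                     controlling: list[str] | None = None,
                     alpha: float = 0.05,
                     min_abs_logfc: float = 1.0):
    """Predicted-vs-observed sign agreement on an expression matrix.

    For each controlling gene i, samples are split at i's median into
    high/low; for every target j with a signed predicted code the log2
    fold change (high over low) and a Welch t-test are computed.  A pair
    is *evaluable* when the split is non-degenerate (>= 2 samples per
    level), both level means are positive, the t-test reaches ``alpha``
    and the fold change is an obvious one (|logFC| >= ``min_abs_logfc``,
    default two-fold — genes whose expression barely moves across the
    split carry no sign information); it is *conformant* when
    sign(logFC) == sign(code).  Code 5 carries no sign and is skipped.
    No multiple-testing correction is applied.

    Returns ``(rate, per_pair_table)``; rate is conformant / evaluable.
    """
    if expr.shape[0] < 4:
        raise ValueError("need >= 4 samples for a high/low split")
    if controlling is None:
        controlling = [n for n in effects.nodes if n in expr.columns]
    rows = []
    n_conformant = n_evaluable = 0
    for i in controlling:
        if i not in expr.columns:
            logger.warning("controlling gene %s absent from matrix; skipped", i)
            continue
        vi = expr[i].to_numpy(dtype=float)
        high, low = _split_high_low(vi)
        if high.sum() < 2 or low.sum() < 2:
            logger.warning("degenerate median split for %s; skipped", i)
            continue
        for j in effects.nodes:
            code = effects.code(i, j)
            if code == 0 or code == 5 or j == i or j not in expr.columns:
                continue
            vj = expr[j].to_numpy(dtype=float)
            m_hi, m_lo = vj[high].mean(), vj[low].mean()
            if m_hi <= 0 or m_lo <= 0:
                rows.append({"controlling": i, "target": j, "code": code,
                             "logFC": np.nan, "p": np.nan, "status": "nonpositive"})
                continue
            logfc = float(np.log2(m_hi / m_lo))
            t, p = sps.ttest_ind(vj[high], vj[low], equal_var=False)
            if not np.isfinite(p) or p >= alpha:
                status = "not-significant"
            elif abs(logfc) < min_abs_logfc:
                status = "no-obvious-change"
            else:
                n_evaluable += 1
                ok = (logfc > 0) == (code > 0)
                n_conformant += int(ok)
                status = "conformant" if ok else "discordant"
            rows.append({"controlling": i, "target": j, "code": code,
                         "logFC": logfc, "p": float(p), "status": status})
    rate = n_conformant / n_evaluable if n_evaluable else float("nan")
    return rate, pd.DataFrame(rows)


def multi_dataset_consistency(effects: EffectMatrix,
                              datasets: list[pd.DataFrame],
                              controlling: list[str] | None = None,
                              alpha: float = 0.05,
                              min_conforming: int = 2) -> pd.DataFrame:
    """Cross-dataset convention: a pair counts consistent when more than
    one dataset conforms (``min_conforming`` defaults to 2).  Returns a
    per-pair table with per-dataset tallies and the final verdict."""
    tables = []
    for d, expr in enumerate(datasets):
        _, tab = consistency_rate(effects, expr, controlling, alpha)
        tab = tab.assign(dataset=d)
        tables.append(tab)
    allt = pd.concat(tables, ignore_index=True)
    evaluated = allt[allt.status.isin(["conformant", "discordant"])]
    out = (evaluated.groupby(["controlling", "target", "code"])
           .agg(n_evaluated=("status", "size"),
                n_conformant=("status", lambda s: int((s == "conformant").sum())))
           .reset_index())
    out["consistent"] = out.n_conformant >= min_conforming
    return out
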