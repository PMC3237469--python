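"""Ordered recursive partitioning: entropy-maximizing cuts on a fixed
variable sequence.

This is the analytical core.  Unlike general CART, the variable split at
each level is fixed in advance — collapse→CPR time first, then
collapse→ambulance, then collapse→hospital (or collapse→ROSC in the
subgroup) — and only the cut point is learned.  Each cut maximizes the
Shannon-entropy information gain for a binary one-month outcome:

    gain(c) = H(p) - [n_L * H(p_L) + n_R * H(p_R)] / n,
    H(p)    = -p log2 p - (1-p) log2 (1-p),   H(0) = H(1) = 0,

over candidate cuts at midpoints between consecutive distinct observed
values (with whole-minute data, every integer boundary).  After each split
the chain descends into the child with the *higher* outcome proportion —
the "within threshold" branch — so the final node is the set of patients
with every interval within its acceptable threshold.  The acceptable
threshold itself is ``floor(cut)``: the largest whole minute on the
favorable (<=) side, i.e. "within 5 min" includes minute 5.

Ties in gain break toward the smallest cut (the conservative,
earliest-time recommendation).  There is no pruning, no multiway split and
no covariate splitting: one split per listed variable, stopping early on
zero gain or an undersized child node.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .registry_io import Cohort, OHCARecord

__all__ = [
    "BinaryOutcomeSpec",
    "FAVORABLE_CPC",
    "SURVIVAL_1MO",
    "OUTCOMES",
    "SplitNode",
    "OrderedPartitionModel",
    "binary_entropy",
    "split_gain",
    "best_cut",
    "fit_ordered_partition",
    "assign_final_node",
]

#: gains below this are treated as zero (exact ties of float arithmetic).
GAIN_TOL = 1e-12


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinaryOutcomeSpec:
    """A named binary outcome evaluated per record over the cohort frame."""

    name: str
    predicate: Callable[[pd.DataFrame], pd.Series]

    def values(self, df: pd.DataFrame) -> np.ndarray:
        """Boolean outcome vector; raises if undefined for any record."""
        series = self.predicate(df)
        if series.isna().any():
            raise ValueError(
                f"outcome {self.name!r} undefined for "
                f"{int(series.isna().sum())} record(s)"
            )
        return series.to_numpy(dtype=bool, na_value=False)


#: Neurologically favorable outcome: Cerebral Performance Category 1 or 2.
FAVORABLE_CPC = BinaryOutcomeSpec("favorable_cpc", lambda df: df["cpc"].isin([1, 2]).mask(df["cpc"].isna()))
#: Alive at one month.
SURVIVAL_1MO = BinaryOutcomeSpec("survival_1mo", lambda df: df["survival_1mo"])

OUTCOMES: dict[str, BinaryOutcomeSpec] = {
    o.name: o for o in (FAVORABLE_CPC, SURVIVAL_1MO)
}


# ---------------------------------------------------------------------------
# Entropy machinery
# ---------------------------------------------------------------------------


def binary_entropy(p):
    """Shannon entropy of a Bernoulli(p), in bits; H(0) = H(1) = 0.

    Accepts scalars or arrays; symmetric, maximal (1 bit) at p = 1/2.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportion outside [0, 1]")
    h = -(xlogy(arr, arr) + xlogy(1.0 - arr, 1.0 - arr)) / math.log(2.0)
    return float(h) if np.isscalar(p) or arr.ndim == 0 else h


def split_gain(values, outcomes, cut: float) -> float:
    """Information gain of splitting at ``value <= cut`` vs ``> cut``.

    Non-negative; zero exactly when both branches share the parent
    proportion.  Raises on an empty branch (the cut is outside the data).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if v.shape != y.shape or v.size < 2:
        raise ValueError("values and outcomes must be equal-length, size >= 2")
    left = v <= cut
    n_left = int(left.sum())
    if n_left == 0 or n_left == v.size:
        raise ValueError(f"cut {cut} leaves an empty branch")
    p = y.mean()
    p_left = y[left].mean()
    p_right = y[~left].mean()
    gain = binary_entropy(p) - (
        n_left * binary_entropy(p_left) + (v.size - n_left) * binary_entropy(p_right)
    ) / v.size
    return max(0.0, float(gain))


@dataclass
class SplitNode:
    """One variable's optimal binary cut and the bookkeeping around it.

    ``acceptable_threshold`` is the largest whole minute on the favorable
    (``<= cut``) side; ``continued_branch`` is the child the ordered chain
    descends into (the one with the higher outcome proportion).
    """

    variable: Optional[str]
    cut: float
    acceptable_threshold: int
    gain: float
    n_parent: int
    n_left: int
    n_right: int
    p_left: float
    p_right: float
    continued_branch: str

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "cut": self.cut,
            "acceptable_threshold": self.acceptable_threshold,
            "gain": self.gain,
            "n_parent": self.n_parent,
            "n_left": self.n_left,
            "n_right": self.n_right,
            "p_left": self.p_left,
            "p_right": self.p_right,
            "continued_branch": self.continued_branch,
        }


@dataclass
class NoSplit:
    """Outcome of ``best_cut`` when no informative cut exists."""

    reason: str  # "constant_values" | "zero_gain" | "node_too_small"


def best_cut(
    values, outcomes, variable: Optional[str] = None, min_child: int = 1
) -> SplitNode | NoSplit:
    """Exhaustive best entropy-gain cut over midpoints of distinct values.

    ``min_child`` restricts the candidate set to cuts leaving at least that
    many records in each child (the usual minimum-bucket rule).  Returns
    :class:`NoSplit` (never raises) when all values are identical, when no
    candidate respects ``min_child``, or when no cut has positive gain (e.g.
    a constant outcome).  Gain ties break toward the smallest cut.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if v.shape != y.shape or v.size < 2:
        raise ValueError("values and outcomes must be equal-length, size >= 2")
    order = np.argsort(v, kind="stable")
    v_sorted = v[order]
    y_sorted = y[order].astype(float)
    boundaries = np.nonzero(np.diff(v_sorted))[0]  # split after these positions
    if boundaries.size == 0:
        return NoSplit("constant_values")
    n = v.size
    if min_child > 1:
        boundaries = boundaries[
            (boundaries + 1 >= min_child) & (n - boundaries - 1 >= min_child)
        ]
        if boundaries.size == 0:
            return NoSplit("node_too_small")
    cum = np.cumsum(y_sorted)
    k_total = cum[-1]
    n_left = boundaries + 1
    k_left = cum[boundaries]
    n_right = n - n_left
    k_right = k_total - k_left
    p_left = k_left / n_left
    p_right = k_right / n_right
    h_parent = binary_entropy(k_total / n)
    gains = h_parent - (n_left * binary_entropy(p_left) + n_right * binary_entropy(p_right)) / n
    gains = np.maximum(gains, 0.0)
    best_gain = float(gains.max())
    if best_gain <= GAIN_TOL:
        return NoSplit("zero_gain")
    # first index within tolerance of the max = smallest cut (cuts ascend)
    idx = int(np.nonzero(gains >= best_gain - GAIN_TOL)[0][0])
    cut = float((v_sorted[boundaries[idx]] + v_sorted[boundaries[idx] + 1]) / 2.0)
    pl, pr = float(p_left[idx]), float(p_right[idx])
    return SplitNode(
        variable=variable,
        cut=cut,
        acceptable_threshold=int(math.floor(cut)),
        gain=float(gains[idx]),
        n_parent=n,
        n_left=int(n_left[idx]),
        n_right=int(n_right[idx]),
        p_left=pl,
        p_right=pr,
        continued_branch="left" if pl >= pr else "right",
    )


# ---------------------------------------------------------------------------
# The ordered chain
# ---------------------------------------------------------------------------


@dataclass
class OrderedPartitionModel:
    """Chain of one split per variable, in a forced order.

    ``stopping`` records, per variable, one of ``split`` / ``zero_gain`` /
    ``node_too_small`` / ``constant_values`` / ``not_reached``.  The model's
    acceptable thresholds (variable → whole minutes) define the final node:
    every split variable at or below its threshold.
    """

    outcome_name: str
    variable_sequence: tuple[str, ...]
    nodes: list[SplitNode]
    stopping: dict[str, str]
    min_node: int

    @property
    def thresholds(self) -> dict[str, int]:
        return {n.variable: n.acceptable_threshold for n in self.nodes}

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome_name,
            "variable_sequence": list(self.variable_sequence),
            "min_node": self.min_node,
            "nodes": [n.to_dict() for n in self.nodes],
            "stopping": dict(self.stopping),
            "acceptable_thresholds": self.thresholds,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "OrderedPartitionModel":
        nodes = [SplitNode(**n) for n in data["nodes"]]
        return cls(
            outcome_name=data["outcome"],
            variable_sequence=tuple(data["variable_sequence"]),
            nodes=nodes,
            stopping=dict(data["stopping"]),
            min_node=int(data["min_node"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "OrderedPartitionModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def render_text(self) -> str:
        """Indented text tree: each level shows both children, the chain
        descending into the continued branch."""
        lines = [f"outcome: {self.outcome_name}"]
        indent = ""
        for node in self.nodes:
            t = node.acceptable_threshold
            rows = [
                ("left", f"{node.variable} <= {t}", node.n_left, node.p_left),
                ("right", f"{node.variable} > {t}", node.n_right, node.p_right),
            ]
            lines.append(
                f"{indent}[n = {node.n_parent:,}] split {node.variable} at "
                f"{node.cut:g} (gain {node.gain:.5f} bits)"
            )
            for side, label, n_side, p_side in rows:
                marker = " *" if side == node.continued_branch else ""
                lines.append(f"{indent}  {label}: n = {n_side:,}, p = {p_side:.4f}{marker}")
            indent += "    "
        for var, reason in self.stopping.items():
            if reason != "split":
                lines.append(f"{indent}({var}: {reason})")
        return "\n".join(lines)


def fit_ordered_partition(
    cohort: Cohort,
    outcome: BinaryOutcomeSpec | str,
    variable_sequence: Sequence[str],
    min_node: int = 50,
) -> OrderedPartitionModel:
    """Fit the ordered chain: one entropy-maximizing cut per listed variable.

    For each variable in order, the best cut is found on the *current* node's
    records — among cuts leaving at least ``min_node`` records in each child
    — and the chain descends into the child with the higher outcome
    proportion.  Fitting stops early (reason recorded) when no cut has
    positive gain, when no cut respects ``min_node``, or when the node's
    values are constant.  Deterministic: there is no randomness in the
    fitter.
    """
    if isinstance(outcome, str):
        outcome = OUTCOMES[outcome]
    if len(cohort) == 0:
        raise ValueError("cannot fit on an empty cohort")
    if min_node < 2:
        raise ValueError("min_node must be >= 2")
    if not variable_sequence:
        raise ValueError("variable_sequence must be non-empty")
    df = cohort.df
    y_all = outcome.values(df)
    mask = np.ones(len(df), dtype=bool)
    nodes: list[SplitNode] = []
    stopping: dict[str, str] = {}
    stopped = False
    for variable in variable_sequence:
        if stopped:
            stopping[variable] = "not_reached"
            continue
        col = df[variable]
        if col.isna().any():
            raise ValueError(
                f"{variable} missing for {int(col.isna().sum())} record(s); "
                "apply time-plausibility filtering first"
            )
        values = col.to_numpy(dtype=float)[mask]
        result = best_cut(values, y_all[mask], variable=variable, min_child=min_node)
        if isinstance(result, NoSplit):
            stopping[variable] = result.reason
            stopped = True
            continue
        stopping[variable] = "split"
        nodes.append(result)
        in_left = df[variable].to_numpy(dtype=float, na_value=np.nan) <= result.cut
        mask &= in_left if result.continued_branch == "left" else ~in_left
    return OrderedPartitionModel(
        outcome_name=outcome.name,
        variable_sequence=tuple(variable_sequence),
        nodes=nodes,
        stopping=stopping,
        min_node=min_node,
    )


def assign_final_node(
    model: OrderedPartitionModel, record: OHCARecord | pd.DataFrame
):
    """Is a record inside the final ("all intervals acceptable") node?

    True iff every split variable is at or below its acceptable threshold
    (the boundary minute is inside).  A missing split variable yields a
    pandas ``NA`` (not-evaluable), which callers count separately.  Accepts a
    single record or a cohort frame (vectorized, returns a nullable boolean
    Series).
    """
    thresholds = model.thresholds
    if isinstance(record, OHCARecord):
        vals = {v: getattr(record, v) for v in thresholds}
        if any(val is None for val in vals.values()):
            return pd.NA
        return all(vals[v] <= t for v, t in thresholds.items())
    df = record
    result = pd.Series(True, index=df.index, dtype="boolean")
    for variable, threshold in thresholds.items():
        result &= df[variable] <= threshold
    return result
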