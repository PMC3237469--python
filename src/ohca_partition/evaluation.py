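"""Validation-set evaluation of a fitted ordered partition model.

Routes every evaluable record through the fitted chain, yielding one
"off-branch" group per split plus the final node (all intervals within
their acceptable thresholds), each with its outcome proportion and a 95%
Wilson score interval.  Wilson rather than Wald because final nodes can be
small and near-zero proportions are common in arrest registries.  The
final-node-vs-rest comparison is a Pearson chi-square on the 2x2 table,
one degree of freedom, no continuity correction.

Percentages render to one decimal with half-up rounding, the style arrest
registries print (209/2,292 -> 9.1%).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.proportion import proportion_confint

from .partition_model import OrderedPartitionModel, OUTCOMES
from .registry_io import Cohort

__all__ = [
    "Proportion",
    "NodeEvaluation",
    "TwoProportionResult",
    "render_percent",
    "outcome_proportion",
    "evaluate_model",
    "compare_final_node",
]


def render_percent(proportion: float) -> float:
    """Render a proportion as a percentage, one decimal, round half up.

    Uses exact decimal arithmetic so e.g. 0.15 % renders as 0.2, not 0.1.
    """
    return float(
        (Decimal(str(proportion)) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class Proportion:
    """n_outcome / n with the registry's percent rendering attached."""

    n_outcome: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 0 or not 0 <= self.n_outcome <= max(self.n, 0):
            raise ValueError("require 0 <= n_outcome <= n")

    @property
    def defined(self) -> bool:
        return self.n > 0

    @property
    def value(self) -> Optional[float]:
        return self.n_outcome / self.n if self.defined else None

    @property
    def pct(self) -> Optional[float]:
        if not self.defined:
            return None
        return float(
            (Decimal(self.n_outcome) * 100 / Decimal(self.n)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )

    def __str__(self) -> str:
        if not self.defined:
            return "0/0 (undefined)"
        return f"{self.n_outcome:,}/{self.n:,} ({self.pct}%)"


def outcome_proportion(n_outcome: int, n: int) -> Proportion:
    """Exact proportion with percent rendering; ``n = 0`` is an undefined
    marker, not an error."""
    return Proportion(n_outcome, n)


def _wilson(k: int, n: int) -> tuple[Optional[float], Optional[float]]:
    if n == 0:
        return None, None
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


@dataclass
class NodeEvaluation:
    """Per-node outcome proportions on one cohort.

    ``rows``: node label, n, n_outcome, proportion, pct, ci_low, ci_high.
    Node labels are ``outside:<variable>`` for each off-branch group (records
    leaving the chain at that split) and ``final_node`` for the chain's end;
    the labelled groups partition the evaluable records.
    """

    outcome_name: str
    provenance: str
    rows: pd.DataFrame
    n_total: int
    n_not_evaluable: int

    @property
    def final_node(self) -> Proportion:
        r = self.rows[self.rows["node"] == "final_node"].iloc[0]
        return Proportion(int(r["n_outcome"]), int(r["n"]))

    def node(self, label: str) -> Proportion:
        r = self.rows[self.rows["node"] == label].iloc[0]
        return Proportion(int(r["n_outcome"]), int(r["n"]))

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [
            f"evaluation of outcome {self.outcome_name!r} on {self.provenance} "
            f"(n = {self.n_total:,}, not evaluable: {self.n_not_evaluable:,})"
        ]
        for _, r in self.rows.iterrows():
            prop = Proportion(int(r["n_outcome"]), int(r["n"]))
            ci = (
                f" [95% CI {r['ci_low']:.3f}-{r['ci_high']:.3f}]"
                if pd.notna(r["ci_low"])
                else ""
            )
            lines.append(f"  {r['node']:<18s} {prop}{ci}")
        return "\n".join(lines)


def evaluate_model(model: OrderedPartitionModel, cohort: Cohort) -> NodeEvaluation:
    """Assign every evaluable record through the chain and tabulate outcomes.

    A record is not evaluable when a split variable or the outcome itself is
    missing; those are counted separately and the remaining node counts
    partition the evaluable set.  Evaluating the derivation cohort itself
    reproduces the fitted nodes' counts and proportions exactly.
    """
    if len(cohort) == 0:
        raise ValueError("cannot evaluate on an empty cohort")
    df = cohort.df
    outcome = OUTCOMES[model.outcome_name]
    y_raw = outcome.predicate(df)
    evaluable = ~y_raw.isna().to_numpy()
    for node in model.nodes:
        evaluable &= ~df[node.variable].isna().to_numpy()
    y = y_raw.to_numpy(dtype=bool, na_value=False)

    rows = []
    current = evaluable.copy()
    for node in model.nodes:
        in_left = df[node.variable].to_numpy(dtype=float, na_value=np.nan) <= node.cut
        continued = in_left if node.continued_branch == "left" else ~in_left
        off = current & ~continued
        k, n = int(y[off].sum()), int(off.sum())
        lo, hi = _wilson(k, n)
        rows.append(
            dict(node=f"outside:{node.variable}", n=n, n_outcome=k,
                 proportion=(k / n if n else None), pct=(render_percent(k / n) if n else None),
                 ci_low=lo, ci_high=hi)
        )
        current &= continued
    k, n = int(y[current].sum()), int(current.sum())
    lo, hi = _wilson(k, n)
    rows.append(
        dict(node="final_node", n=n, n_outcome=k,
             proportion=(k / n if n else None), pct=(render_percent(k / n) if n else None),
             ci_low=lo, ci_high=hi)
    )
    return NodeEvaluation(
        outcome_name=model.outcome_name,
        provenance=cohort.provenance,
        rows=pd.DataFrame(rows),
        n_total=len(df),
        n_not_evaluable=int((~evaluable).sum()),
    )


@dataclass(frozen=True)
class TwoProportionResult:
    """Pearson chi-square (1 df, no continuity correction) on final node vs
    the rest.  ``testable`` is False when either group is empty."""

    testable: bool
    statistic: Optional[float] = None
    p_value: Optional[float] = None
    table: Optional[tuple[tuple[int, int], tuple[int, int]]] = None


def compare_final_node(evaluation: NodeEvaluation) -> TwoProportionResult:
    """Chi-square comparison of the final node against all other nodes."""
    final = evaluation.final_node
    others = evaluation.rows[evaluation.rows["node"] != "final_node"]
    k_rest = int(others["n_outcome"].sum())
    n_rest = int(others["n"].sum())
    if final.n == 0 or n_rest == 0:
        return TwoProportionResult(testable=False)
    table = (
        (final.n_outcome, final.n - final.n_outcome),
        (k_rest, n_rest - k_rest),
    )
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any():
        # a zero column (e.g. no events anywhere): expected counts vanish
        return TwoProportionResult(testable=False, table=table)
    stat, p, _, _ = chi2_contingency(arr, correction=False)
    return TwoProportionResult(True, float(stat), float(p), table)
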