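"""Inclusion/exclusion cascade and time-plausibility windows with audit ledger.

The analysis cohort is carved out of a raw registry in two passes:

1. an ordered inclusion cascade — witnessed arrest, bystander CPR given, not
   mouth-to-mouth-only, adult, required fields present — where a record is
   counted under the *first* rule it fails, so per-rule exclusion counts are
   disjoint exactly as a study-profile flow diagram reports them;
2. time-plausibility windows: an interval that is negative or implausibly
   long (by default beyond 20/40/80 min for collapse→CPR, collapse→ambulance
   and collapse→hospital) marks the whole record as unusable.  Boundary
   values are kept: "minus or greater than 20" excludes t < 0 and t > 20,
   leaving t = 20 inside.

Every pass returns a :class:`FilterReport` whose rows telescope (each
remaining count equals the previous minus that rule's exclusions), which is
property-tested rather than trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .registry_io import Cohort

__all__ = [
    "FilterRule",
    "FilterReport",
    "PlausibilityWindows",
    "INCLUSION_RULES",
    "apply_rules",
    "apply_inclusion_cascade",
    "apply_time_plausibility",
    "select_rosc_subgroup",
]


@dataclass(frozen=True)
class FilterRule:
    """One exclusion criterion: ``fails(df)`` flags records to drop."""

    name: str
    description: str
    fails: Callable[[pd.DataFrame], np.ndarray]


@dataclass
class FilterReport:
    """Ordered ledger of (rule, n_excluded, n_remaining) rows.

    Invariant (``validate()``): the rows telescope — each ``n_remaining``
    equals the previous remaining count minus ``n_excluded``, and the final
    count is the initial count minus the summed exclusions.
    """

    initial: int
    rows: list[tuple[str, int, int]] = field(default_factory=list)
    diagnostics: dict[str, int] = field(default_factory=dict)

    @property
    def final(self) -> int:
        return self.rows[-1][2] if self.rows else self.initial

    def validate(self) -> None:
        prev = self.initial
        for name, excluded, remaining in self.rows:
            if remaining != prev - excluded:
                raise ValueError(f"telescoping violated at rule {name!r}")
            prev = remaining
        if self.final != self.initial - sum(r[1] for r in self.rows):
            raise ValueError("final count does not telescope")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rule", "n_excluded", "n_remaining"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_text(self) -> str:
        """Plain-text flow diagram in study-profile style."""
        lines = [f"{self.initial:>9,}  records"]
        for name, excluded, remaining in self.rows:
            lines.append(f"          |-- excluded {excluded:>9,}  ({name})")
            lines.append(f"{remaining:>9,}  remaining")
        for key, val in self.diagnostics.items():
            lines.append(f"          [{key}: {val:,}]")
        return "\n".join(lines)


def _na_or(mask: pd.Series) -> np.ndarray:
    return mask.to_numpy(dtype=bool, na_value=False)


def _required_missing(df: pd.DataFrame) -> np.ndarray:
    cols = ["witnessed", "bystander_cpr", "age", "survival_1mo", "cpc"]
    return df[cols].isna().any(axis=1).to_numpy()


#: The inclusion cascade, in reporting order.
INCLUSION_RULES: tuple[FilterRule, ...] = (
    FilterRule(
        "not_witnessed",
        "arrest not witnessed by a bystander",
        lambda df: _na_or(df["witnessed"] == False),  # noqa: E712
    ),
    FilterRule(
        "no_bystander_cpr",
        "no bystander CPR performed",
        lambda df: _na_or(df["bystander_cpr"] == "none"),
    ),
    FilterRule(
        "mouth_to_mouth_only",
        "bystander CPR was mouth-to-mouth ventilation only",
        lambda df: _na_or(df["bystander_cpr"] == "mouth_to_mouth_only"),
    ),
    FilterRule(
        "age_under_18",
        "17 years of age or younger",
        lambda df: _na_or(df["age"] < 18),
    ),
    FilterRule(
        "missing_required",
        "missing witness status, CPR type, age or outcome data",
        _required_missing,
    ),
)


@dataclass(frozen=True)
class PlausibilityWindows:
    """Upper bounds (minutes) on collapse-anchored intervals; lower bound 0.

    A boundary value is kept (t == max is plausible).  ``max_t_rosc`` governs
    the pre-hospital ROSC subgroup and defaults to the hospital window, the
    widest time still observable before hospital arrival.
    """

    max_t_cpr: int = 20
    max_t_amb: int = 40
    max_t_hosp: int = 80
    max_t_rosc: Optional[int] = None

    @property
    def rosc_bound(self) -> int:
        return self.max_t_hosp if self.max_t_rosc is None else self.max_t_rosc


def apply_rules(
    cohort: Cohort, rules: Sequence[FilterRule], provenance: str
) -> tuple[Cohort, FilterReport]:
    """Apply rules in order, attributing each record to its first failure."""
    df = cohort.df
    report = FilterReport(initial=len(df))
    alive = np.ones(len(df), dtype=bool)
    for rule in rules:
        fails = rule.fails(df) & alive
        alive &= ~fails
        report.rows.append((rule.name, int(fails.sum()), int(alive.sum())))
    report.validate()
    return cohort.subset(alive, provenance), report


def apply_inclusion_cascade(cohort: Cohort) -> tuple[Cohort, FilterReport]:
    """Witnessed, bystander-CPR, CPR-type, adult-age and completeness rules.

    A record failing several rules is counted once, under the first rule in
    reporting order; an empty result is legal and reported, never an error.
    """
    return apply_rules(cohort, INCLUSION_RULES, provenance=f"{cohort.provenance}|eligible")


def _window_fail(
    df: pd.DataFrame, column: str, upper: int
) -> tuple[np.ndarray, dict[str, int]]:
    vals = df[column]
    missing = vals.isna().to_numpy()
    out_low = _na_or(vals < 0)
    out_high = _na_or(vals > upper)
    diag = {
        f"{column}_missing": int(missing.sum()),
        f"{column}_negative": int(out_low.sum()),
        f"{column}_over_{upper}": int(out_high.sum()),
    }
    return missing | out_low | out_high, diag


def apply_time_plausibility(
    cohort: Cohort, windows: PlausibilityWindows = PlausibilityWindows()
) -> tuple[Cohort, FilterReport]:
    """Drop records whose time data are inconceivable (or absent).

    One combined report row; per-window diagnostic counts (missing, negative,
    over-window) are kept separately since a record can breach several
    windows at once.
    """
    df = cohort.df
    fails = np.zeros(len(df), dtype=bool)
    diagnostics: dict[str, int] = {}
    for column, upper in (
        ("t_cpr", windows.max_t_cpr),
        ("t_amb", windows.max_t_amb),
        ("t_hosp", windows.max_t_hosp),
    ):
        f, diag = _window_fail(df, column, upper)
        fails |= f
        diagnostics.update(diag)
    report = FilterReport(initial=len(df))
    report.rows.append(("implausible_time", int(fails.sum()), int((~fails).sum())))
    report.diagnostics = diagnostics
    report.validate()
    return cohort.subset(~fails, f"{cohort.provenance}|plausible"), report


def select_rosc_subgroup(
    cohort: Cohort, windows: PlausibilityWindows = PlausibilityWindows()
) -> tuple[Cohort, FilterReport]:
    """Pre-hospital ROSC subgroup: ROSC recorded, ROSC time plausible.

    Keeps records with ``t_rosc`` present, then applies the three primary
    windows plus ``0 <= t_rosc <= windows.rosc_bound`` (a configurable
    assumption; the subgroup's own plausibility window is not standardized).
    """
    df = cohort.df
    no_rosc = df["t_rosc"].isna().to_numpy()
    report = FilterReport(initial=len(df))
    report.rows.append(("no_prehospital_rosc", int(no_rosc.sum()), int((~no_rosc).sum())))

    fails = np.zeros(len(df), dtype=bool)
    diagnostics: dict[str, int] = {}
    for column, upper in (
        ("t_cpr", windows.max_t_cpr),
        ("t_amb", windows.max_t_amb),
        ("t_hosp", windows.max_t_hosp),
        ("t_rosc", windows.rosc_bound),
    ):
        f, diag = _window_fail(df, column, upper)
        fails |= f
        diagnostics.update(diag)
    fails &= ~no_rosc
    report.rows.append(("implausible_time", int(fails.sum()), int((~no_rosc & ~fails).sum())))
    report.diagnostics = diagnostics
    report.validate()
    keep = ~no_rosc & ~fails
    return cohort.subset(keep, f"{cohort.provenance}|rosc_subgroup"), report
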