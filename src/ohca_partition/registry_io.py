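"""Utstein-style cardiac-arrest registry records: schema, CSV I/O, summaries.

A cohort is one row per out-of-hospital cardiac-arrest (OHCA) patient:
demographics, bystander/EMS covariates, whole-minute time intervals anchored
at collapse, and one-month outcomes (survival, Cerebral Performance Category).
The national registries this emulates are not publicly deposited, so the
reader is dialect-driven (a column-mapping config) rather than hard-coded to
any file layout.

Conventions fixed here and relied on everywhere else:

* Intervals are signed whole minutes; negative values are representable
  because raw registries contain them (they are *filtered*, not rejected,
  downstream in :mod:`ohca_partition.cohort_filter`).
* Missing is an empty cell on disk and a pandas ``NA`` in memory.  The
  ``unknown`` level of ``sex`` is a real category, distinct from missing.
* Quantiles use the lower nearest-rank rule (see :func:`nearest_rank_quantile`):
  whole-minute data make interpolation conventions visible, so one rule is
  fixed and documented.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "OHCARecord",
    "Cohort",
    "CohortSummary",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
    "load_dialect",
    "nearest_rank_quantile",
    "COLUMN_ORDER",
    "CATEGORY_LEVELS",
]


class RegistryConfigError(ValueError):
    """Raised for malformed dialects or headers that do not match them."""


class EmptyInputError(ValueError):
    """Raised when a cohort file contains no data rows."""


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female", "unknown"),
    "bystander_cpr": (
        "none",
        "chest_compression_only",
        "conventional",
        "mouth_to_mouth_only",
    ),
    "bystander_category": (
        "family",
        "friend",
        "colleague",
        "passerby",
        "other_layperson",
        "healthcare_provider",
        "other",
    ),
    "initial_rhythm": ("VF", "pulseless_VT", "PEA", "asystole", "other"),
    "airway_tool": ("LM", "esophageal_obturator", "intubation", "none"),
    "defibrillator_kind": ("monophasic", "biphasic", "none"),
}

BOOL_COLUMNS: tuple[str, ...] = (
    "witnessed",
    "aed_by_bystander",
    "dispatcher_assist",
    "dc_by_ems",
    "iv_by_ems",
    "epinephrine_by_ems",
    "cardiac_cause",
    "survival_1mo",
)

INTERVAL_COLUMNS: tuple[str, ...] = ("t_cpr", "t_amb", "t_hosp", "t_rosc")

INT_COLUMNS: tuple[str, ...] = ("age", "cpc") + INTERVAL_COLUMNS

#: Stable on-disk column order.
COLUMN_ORDER: tuple[str, ...] = (
    "age",
    "sex",
    "witnessed",
    "bystander_cpr",
    "bystander_category",
    "aed_by_bystander",
    "dispatcher_assist",
    "initial_rhythm",
    "dc_by_ems",
    "defibrillator_kind",
    "airway_tool",
    "iv_by_ems",
    "epinephrine_by_ems",
    "cardiac_cause",
    "t_cpr",
    "t_amb",
    "t_hosp",
    "t_rosc",
    "survival_1mo",
    "cpc",
)


@dataclass(frozen=True)
class OHCARecord:
    """One patient's covariates, collapse-anchored intervals and outcomes.

    Invariants (checked by :meth:`Cohort.check_invariants`, not enforced at
    construction because raw registry rows may violate them before filtering):

    * ``cpc`` in 1..5 when present; CPC 1-2 is the neurologically favorable
      outcome, CPC 5 means dead at one month.
    * ``cpc`` in 1..4 implies ``survival_1mo``.
    """

    age: Optional[int] = None
    sex: Optional[str] = None
    witnessed: Optional[bool] = None
    bystander_cpr: Optional[str] = None
    bystander_category: Optional[str] = None
    aed_by_bystander: Optional[bool] = None
    dispatcher_assist: Optional[bool] = None
    initial_rhythm: Optional[str] = None
    dc_by_ems: Optional[bool] = None
    defibrillator_kind: Optional[str] = None
    airway_tool: Optional[str] = None
    iv_by_ems: Optional[bool] = None
    epinephrine_by_ems: Optional[bool] = None
    cardiac_cause: Optional[bool] = None
    t_cpr: Optional[int] = None
    t_amb: Optional[int] = None
    t_hosp: Optional[int] = None
    t_rosc: Optional[int] = None
    survival_1mo: Optional[bool] = None
    cpc: Optional[int] = None

    @property
    def favorable_cpc(self) -> Optional[bool]:
        """CPC 1 or 2 at one month; ``None`` when CPC is missing."""
        if self.cpc is None:
            return None
        return self.cpc in (1, 2)


def _empty_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=_dtype_for(c)) for c in COLUMN_ORDER})
    return df


def _dtype_for(column: str) -> str:
    if column in INT_COLUMNS:
        return "Int32"
    if column in BOOL_COLUMNS:
        return "boolean"
    return "string"


@dataclass
class Cohort:
    """An ordered collection of OHCA records backed by a typed DataFrame.

    ``df.index`` carries stable record identities across filtering and
    splitting, so provenance audits (e.g. that a validation set never leaks
    derivation records) reduce to index arithmetic.
    """

    df: pd.DataFrame
    provenance: str
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("cohort provenance must be non-empty")
        missing = [c for c in COLUMN_ORDER if c not in self.df.columns]
        if missing:
            raise RegistryConfigError(f"cohort frame lacks columns: {missing}")
        self.df = self.df[list(COLUMN_ORDER)]

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[OHCARecord]:
        names = [f.name for f in dc_fields(OHCARecord)]
        for row in self.df.itertuples(index=False):
            values = {
                n: (None if pd.isna(v) else v)
                for n, v in zip(COLUMN_ORDER, row)
                if n in names
            }
            for k in INT_COLUMNS:
                if values.get(k) is not None:
                    values[k] = int(values[k])
            for k in BOOL_COLUMNS:
                if values.get(k) is not None:
                    values[k] = bool(values[k])
            yield OHCARecord(**values)

    @classmethod
    def from_records(
        cls,
        records: Sequence[OHCARecord],
        provenance: str,
        source: Optional[str] = None,
    ) -> "Cohort":
        if not records:
            return cls(_empty_frame(), provenance, source)
        raw = {c: [getattr(r, c) for r in records] for c in COLUMN_ORDER}
        df = pd.DataFrame(
            {c: pd.array(v, dtype=_dtype_for(c)) for c, v in raw.items()}
        )
        return cls(df, provenance, source)

    def subset(self, mask: np.ndarray | pd.Series, provenance: str) -> "Cohort":
        """Row subset preserving record identities (index labels)."""
        if isinstance(mask, pd.Series):
            mask = mask.to_numpy(dtype=bool, na_value=False)
        return Cohort(self.df.loc[np.asarray(mask, dtype=bool)], provenance, self.source)

    def check_invariants(self) -> None:
        """Raise ``ValueError`` on any outcome-consistency violation.

        Intended for generated (clean) cohorts; raw registry extracts are
        allowed to violate these until filtered.
        """
        df = self.df
        cpc = df["cpc"]
        bad_cpc = cpc.dropna()[~cpc.dropna().isin([1, 2, 3, 4, 5])]
        if len(bad_cpc):
            raise ValueError(f"CPC outside 1..5 in {len(bad_cpc)} records")
        alive_cpc = cpc.isin([1, 2, 3, 4])
        surv = df["survival_1mo"]
        if bool((alive_cpc & (surv == False)).any()):  # noqa: E712
            raise ValueError("CPC 1-4 recorded for a non-survivor")
        if bool(((cpc == 5) & (surv == True)).any()):  # noqa: E712
            raise ValueError("CPC 5 recorded for a survivor")
        for col, levels in CATEGORY_LEVELS.items():
            vals = df[col].dropna()
            bad = vals[~vals.isin(levels)]
            if len(bad):
                raise ValueError(f"unknown level {bad.iloc[0]!r} in {col}")


# ---------------------------------------------------------------------------
# Dialect-driven CSV I/O
# ---------------------------------------------------------------------------

#: outcome columns whose *presence in the header* is non-negotiable.
REQUIRED_OUTCOME_COLUMNS: tuple[str, ...] = ("survival_1mo", "cpc")


def load_dialect(path: str | Path) -> dict[str, str]:
    """Load a YAML column-mapping dialect ``{file header -> canonical name}``."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in raw.items()
    ):
        raise RegistryConfigError(f"dialect {path} is not a flat string mapping")
    unknown = sorted(set(raw.values()) - set(COLUMN_ORDER))
    if unknown:
        raise RegistryConfigError(f"dialect maps to unknown columns: {unknown}")
    return dict(raw)


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_column(raw: pd.Series, column: str) -> tuple[pd.Series, int]:
    """Parse one string column to its schema dtype; return (values, n_bad)."""
    s = raw.fillna("").str.strip()
    empty = s == ""
    n_bad = 0
    if column in INT_COLUMNS:
        num = pd.to_numeric(s.where(~empty), errors="coerce")
        bad = ~empty & (num.isna() | (num % 1 != 0))
        n_bad = int(bad.sum())
        out = pd.array(num.where(~bad).round(), dtype="Int32")
    elif column in BOOL_COLUMNS:
        low = s.str.lower()
        parsed = pd.Series(pd.NA, index=s.index, dtype="boolean")
        parsed[low.isin(_TRUE)] = True
        parsed[low.isin(_FALSE)] = False
        bad = parsed.isna() & ~empty
        n_bad = int(bad.sum())
        out = parsed.array
    elif column in CATEGORY_LEVELS:
        ok = s.isin(CATEGORY_LEVELS[column])
        bad = ~ok & ~empty
        n_bad = int(bad.sum())
        out = pd.array(s.where(ok), dtype="string")
    else:  # pragma: no cover - schema covers every column
        out = pd.array(s.where(~empty), dtype="string")
    return pd.Series(out, index=raw.index, name=column), n_bad


def read_cohort(
    path: str | Path,
    dialect: Mapping[str, str] | str | Path | None = None,
    provenance: Optional[str] = None,
) -> Cohort:
    """Read a delimited-text cohort.

    ``dialect`` maps file headers to canonical column names (YAML path or
    mapping); by default headers are taken verbatim.  Every canonical column
    must be present after mapping.  Unparseable cells become missing with one
    warning per affected column — except that the outcome *columns* must
    exist (blank outcome cells are legal; the exclusion cascade counts them).
    """
    path = Path(path)
    if dialect is None:
        dialect = {}
    elif not isinstance(dialect, Mapping):
        dialect = load_dialect(dialect)
    raw = pd.read_csv(path, dtype="string", keep_default_na=False, na_values=[""])
    raw = raw.rename(columns=dict(dialect))
    missing_cols = [c for c in COLUMN_ORDER if c not in raw.columns]
    if missing_cols:
        raise RegistryConfigError(
            f"{path}: header lacks required columns {missing_cols} "
            "(check the dialect mapping)"
        )
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    parsed = {}
    for col in COLUMN_ORDER:
        parsed[col], n_bad = _parse_column(raw[col], col)
        if n_bad:
            warnings.warn(
                f"{path}: {n_bad} unparseable value(s) in column {col!r} "
                "treated as missing",
                stacklevel=2,
            )
    df = pd.DataFrame(parsed)
    return Cohort(df, provenance or f"file:{path.name}", source=str(path))


def write_cohort(
    cohort: Cohort, path: str | Path, allow_empty: bool = False
) -> None:
    """Write a cohort as UTF-8 CSV: stable column order, missing as empty cell."""
    if len(cohort) == 0 and not allow_empty:
        raise ValueError("refusing to write an empty cohort (allow_empty=False)")
    out = cohort.df.copy()
    for col in BOOL_COLUMNS:
        out[col] = out[col].map({True: "true", False: "false"}, na_action="ignore")
    out.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def nearest_rank_quantile(values: Sequence[float] | np.ndarray, q: float) -> float:
    """Lower nearest-rank quantile: element at 1-based rank ``ceil(q*n)``.

    With whole-minute data this always returns an observed value, so the
    printed medians/IQRs are attainable minutes rather than interpolations.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    arr = np.sort(np.asarray(values))
    if arr.size == 0:
        raise ValueError("no values")
    rank = max(1, math.ceil(q * arr.size))
    return float(arr[rank - 1])


@dataclass
class CohortSummary:
    """Descriptive rows per variable, in the registry's reporting style.

    ``rows`` columns: variable, level, statistic, value, n, n_missing.
    Continuous age is mean/SD; categoricals are counts with percentages over
    non-missing values; intervals are median and 25th/75th percentiles.
    """

    rows: pd.DataFrame
    n: int

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [f"Cohort summary (n = {self.n:,})", "-" * 46]
        for _, r in self.rows.iterrows():
            label = r["variable"] if pd.isna(r["level"]) else f"{r['variable']}: {r['level']}"
            lines.append(f"{label:<42s} {r['statistic']} = {r['value']}")
        return "\n".join(lines)


def _pct(x: float) -> float:
    from .evaluation import render_percent

    return render_percent(x)


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Descriptive summary mirroring registry characteristic tables.

    Percentages for categoricals are computed over non-missing values (never
    copied from anywhere); an all-missing variable yields a single
    ``no data`` row instead of an error.
    """
    if len(cohort) == 0:
        raise EmptyInputError("cannot summarize an empty cohort")
    df = cohort.df
    rows: list[dict] = []

    def add(variable, level, statistic, value, n, n_missing):
        rows.append(
            dict(
                variable=variable,
                level=level,
                statistic=statistic,
                value=value,
                n=n,
                n_missing=n_missing,
            )
        )

    n_total = len(df)

    age = df["age"].dropna().astype(float)
    if len(age):
        add("age", None, "mean", round(float(age.mean()), 1), len(age), n_total - len(age))
        add("age", None, "sd", round(float(age.std(ddof=1)), 1) if len(age) > 1 else 0.0,
            len(age), n_total - len(age))
    else:
        add("age", None, "no data", None, 0, n_total)

    cat_like = list(CATEGORY_LEVELS) + [c for c in BOOL_COLUMNS] + ["cpc"]
    for col in cat_like:
        vals = df[col].dropna()
        n_missing = n_total - len(vals)
        if not len(vals):
            add(col, None, "no data", None, 0, n_missing)
            continue
        counts = vals.value_counts()
        for level, cnt in counts.items():
            add(col, str(level), "count", int(cnt), len(vals), n_missing)
            add(col, str(level), "percent", _pct(cnt / len(vals)), len(vals), n_missing)

    for col in INTERVAL_COLUMNS:
        vals = df[col].dropna().astype(float).to_numpy()
        n_missing = n_total - len(vals)
        if not len(vals):
            add(col, None, "no data", None, 0, n_missing)
            continue
        add(col, None, "median", nearest_rank_quantile(vals, 0.5), len(vals), n_missing)
        add(col, None, "q1", nearest_rank_quantile(vals, 0.25), len(vals), n_missing)
        add(col, None, "q3", nearest_rank_quantile(vals, 0.75), len(vals), n_missing)

    return CohortSummary(pd.DataFrame(rows), n=n_total)
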