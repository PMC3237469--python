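"""Seeded random partition of a cohort into derivation and validation sets.

The default assignment is per-record Bernoulli(fraction) with a seeded
generator: each patient flips the same coin independently, which is the
mechanism consistent with a single random split producing *unequal* halves
(e.g. 34,605 vs 35,043 out of 69,648).  An exact-count mode (permutation,
``round(fraction * n)`` records to derivation) is available when equal-sized
halves are wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .registry_io import Cohort

__all__ = ["SplitSpec", "random_split"]


@dataclass(frozen=True)
class SplitSpec:
    """Derivation fraction (strictly inside (0,1)), seed and assignment mode."""

    derivation_fraction: float = 0.5
    seed: int = 0
    mode: Literal["bernoulli", "exact"] = "bernoulli"

    def __post_init__(self) -> None:
        if not 0.0 < self.derivation_fraction < 1.0:
            raise ValueError("derivation_fraction must be strictly between 0 and 1")
        if self.mode not in ("bernoulli", "exact"):
            raise ValueError(f"unknown split mode {self.mode!r}")


def random_split(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort]:
    """Partition ``cohort`` into (derivation, validation).

    Every record lands in exactly one part; identical ``(cohort, spec)``
    always reproduce the same partition.  In ``exact`` mode the derivation
    size is ``round(fraction * n)`` (banker's rounding, as Python's round).
    """
    n = len(cohort)
    if n < 2:
        raise ValueError("cannot split a cohort with fewer than 2 records")
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "bernoulli":
        to_derivation = rng.random(n) < spec.derivation_fraction
    else:
        k = round(spec.derivation_fraction * n)
        order = rng.permutation(n)
        to_derivation = np.zeros(n, dtype=bool)
        to_derivation[order[:k]] = True
    derivation = cohort.subset(to_derivation, "derivation")
    validation = cohort.subset(~to_derivation, "validation")
    return derivation, validation
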