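"""End-to-end analysis runs: simulate/ingest → filter → split → fit → evaluate.

Four canonical presets mirror the study design — the neurologically
favorable and survival outcomes, each fit on the full witnessed
bystander-CPR cohort (splitting CPR, ambulance and hospital times) and on
the pre-hospital ROSC subgroup (CPR and ROSC times).  A run writes its
artifact bundle (filter reports, split manifest, model JSON, text trees,
derivation/validation evaluations and a run log with the config hash) into
an output directory, and an identical configuration reproduces the bundle
exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

from . import registry_io
from .cohort_filter import (
    PlausibilityWindows,
    apply_inclusion_cascade,
    apply_time_plausibility,
    select_rosc_subgroup,
)
from .data_split import SplitSpec, random_split
from .evaluation import compare_final_node, evaluate_model
from .partition_model import OUTCOMES, fit_ordered_partition
from .registry_io import Cohort, read_cohort
from .synthetic_data import SyntheticConfig, generate_cohort

__all__ = ["RunConfig", "RunResult", "PRESETS", "run_pipeline"]

#: preset name -> (outcome, variable sequence, rosc subgroup?)
PRESETS: dict[str, tuple[str, tuple[str, ...], bool]] = {
    "favorable_full": ("favorable_cpc", ("t_cpr", "t_amb", "t_hosp"), False),
    "survival_full": ("survival_1mo", ("t_cpr", "t_amb", "t_hosp"), False),
    "favorable_rosc": ("favorable_cpc", ("t_cpr", "t_rosc"), True),
    "survival_rosc": ("survival_1mo", ("t_cpr", "t_rosc"), True),
}


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: data source, model preset and knobs.

    Exactly one of ``input_path`` (a registry CSV) or ``synthetic`` (a
    simulator config) supplies the raw cohort.
    """

    preset: str = "favorable_full"
    input_path: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = SyntheticConfig()
    windows: PlausibilityWindows = PlausibilityWindows()
    split: SplitSpec = SplitSpec()
    min_node: int = 50
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path or synthetic must be set")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory artifact bundle of one pipeline run."""

    config: RunConfig
    cascade_report: object
    plausibility_report: object
    model: object
    derivation_eval: object
    validation_eval: object
    comparison: object
    stage_counts: dict[str, int]

    def summary(self) -> dict:
        final = self.validation_eval.final_node
        return {
            "preset": self.config.preset,
            "config_hash": self.config.config_hash(),
            "stage_counts": self.stage_counts,
            "thresholds": self.model.thresholds,
            "stopping": self.model.stopping,
            "validation_final_node": {
                "n": final.n,
                "n_outcome": final.n_outcome,
                "pct": final.pct,
            },
            "final_node_vs_rest_chi2": self.comparison.statistic,
            "final_node_vs_rest_p": self.comparison.p_value,
        }


def _load_raw(config: RunConfig) -> Cohort:
    if config.input_path is not None:
        return read_cohort(config.input_path)
    cohort, _ = generate_cohort(config.synthetic)
    return cohort


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute one preset end to end; write the bundle when out_dir is set.

    Stage order: inclusion cascade, time plausibility (plus ROSC-subgroup
    selection for subgroup presets), random derivation/validation split, fit
    on derivation only, evaluation on both halves, final-node chi-square on
    the validation half.  The validation evaluation sees only validation
    records — the split is a partition of record identities, audited in the
    run log's stage counts.
    """
    outcome_name, sequence, subgroup = PRESETS[config.preset]
    raw = _load_raw(config)
    eligible, cascade_report = apply_inclusion_cascade(raw)
    if subgroup:
        analysis, plaus_report = select_rosc_subgroup(eligible, config.windows)
    else:
        analysis, plaus_report = apply_time_plausibility(eligible, config.windows)
    derivation, validation = random_split(analysis, config.split)
    model = fit_ordered_partition(
        derivation, OUTCOMES[outcome_name], sequence, min_node=config.min_node
    )
    derivation_eval = evaluate_model(model, derivation)
    validation_eval = evaluate_model(model, validation)
    comparison = compare_final_node(validation_eval)
    stage_counts = {
        "raw": len(raw),
        "eligible": len(eligible),
        "analysis": len(analysis),
        "derivation": len(derivation),
        "validation": len(validation),
    }
    result = RunResult(
        config=config,
        cascade_report=cascade_report,
        plausibility_report=plaus_report,
        model=model,
        derivation_eval=derivation_eval,
        validation_eval=validation_eval,
        comparison=comparison,
        stage_counts=stage_counts,
    )
    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir))
    return result


def _write_bundle(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.cascade_report.to_csv(out / "filter_cascade.csv")
    result.plausibility_report.to_csv(out / "filter_plausibility.csv")
    (out / "filter_flow.txt").write_text(
        result.cascade_report.to_text() + "\n\n" + result.plausibility_report.to_text() + "\n",
        encoding="utf-8",
    )
    result.model.to_json(out / "model.json")
    (out / "tree.txt").write_text(result.model.render_text() + "\n", encoding="utf-8")
    result.derivation_eval.to_csv(out / "evaluation_derivation.csv")
    result.validation_eval.to_csv(out / "evaluation_validation.csv")
    (out / "run_log.json").write_text(
        json.dumps(result.summary(), indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
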