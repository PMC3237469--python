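"""Evaluate the fitted models on the held-out validation halves.

For each canonical model: route every validation record through the fitted
chain, tabulate per-node outcome proportions with 95% Wilson intervals,
and compare the final (all-intervals-acceptable) node against the rest
with a Pearson chi-square.  Writes per-model evaluation CSVs and a summary
table to results/.

Run:  python analysis/04_validate_models.py
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from ohca_partition import compare_final_node, evaluate_model, read_cohort
from ohca_partition.partition_model import OrderedPartitionModel
from ohca_partition.pipeline import PRESETS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    scratch = ROOT / "scratch"
    rows = []
    for preset, (_, _, subgroup) in PRESETS.items():
        model = OrderedPartitionModel.from_json(results / f"model_{preset}.json")
        validation = read_cohort(
            scratch / ("validation_rosc.csv" if subgroup else "validation_full.csv")
        )
        evaluation = evaluate_model(model, validation)
        evaluation.to_csv(results / f"validation_{preset}.csv")
        comparison = compare_final_node(evaluation)
        final = evaluation.final_node
        rows.append(
            dict(
                model=preset,
                thresholds=json.dumps(model.thresholds),
                validation_n=evaluation.n_total,
                final_node=str(final),
                chi2_vs_rest=None if not comparison.testable else round(comparison.statistic, 1),
                p_value=None if not comparison.testable else comparison.p_value,
            )
        )
        print(f"{preset:16s} final node {final}  "
              + (f"chi2 = {comparison.statistic:.1f}, p = {comparison.p_value:.2g}"
                 if comparison.testable else "(not testable)"))
        print(evaluation.to_text())
        print()
    pd.DataFrame(rows).to_csv(results / "validation_summary.csv", index=False)


if __name__ == "__main__":
    main()
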