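"""Apply the eligibility cascade and time-plausibility windows.

Reads the raw simulated registry, applies the witnessed / bystander-CPR /
CPR-type / adult-age / completeness cascade and then drops records with
inconceivable time data (negative, or beyond 20/40/80 min for CPR,
ambulance and hospital intervals).  Also selects the pre-hospital ROSC
subgroup.  Writes the analysis-grade cohorts to scratch/ and the audit
ledgers (study-profile flow) to results/.

Run:  python analysis/02_filter_cohort.py
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ohca_partition import (
    apply_inclusion_cascade,
    apply_time_plausibility,
    read_cohort,
    select_rosc_subgroup,
    summarize_cohort,
    write_cohort,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    raw = read_cohort(ROOT / "scratch" / "registry_raw.csv")
    eligible, cascade = apply_inclusion_cascade(raw)
    analysis, plausibility = apply_time_plausibility(eligible)
    subgroup, sub_report = select_rosc_subgroup(eligible)

    results = ROOT / "results"
    write_cohort(analysis, ROOT / "scratch" / "analysis_cohort.csv")
    write_cohort(subgroup, ROOT / "scratch" / "rosc_subgroup.csv")

    pd.concat(
        [cascade.to_frame(), plausibility.to_frame()], ignore_index=True
    ).to_csv(results / "filter_report_full.csv", index=False)
    sub_report.to_frame().to_csv(results / "filter_report_subgroup.csv", index=False)
    flow = (
        "Full cohort\n" + cascade.to_text() + "\n" + plausibility.to_text()
        + "\n\nPre-hospital ROSC subgroup (from the eligible cohort)\n"
        + sub_report.to_text() + "\n"
    )
    (results / "filter_flow.txt").write_text(flow, encoding="utf-8")
    summarize_cohort(analysis).to_csv(results / "table_analysis_cohort_summary.csv")

    print(flow)
    print(
        f"analysis cohort {len(analysis):,} "
        f"({100 * len(analysis) / cascade.final:.1f}% of eligible); "
        f"rosc subgroup {len(subgroup):,}"
    )


if __name__ == "__main__":
    main()
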