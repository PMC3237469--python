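"""Split the analysis cohort and derive acceptable time thresholds.

Randomly divides the filtered cohort (and the ROSC subgroup) into
derivation and validation halves, then fits the ordered recursive
partition on the derivation half for each of the four canonical models:
favorable outcome and survival, full cohort (CPR → ambulance → hospital)
and ROSC subgroup (CPR → ROSC).  Writes split manifests, model JSON and
text trees to results/, and the four cohort halves to scratch/.

Run:  python analysis/03_derive_thresholds.py [--split-seed S]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from ohca_partition import fit_ordered_partition, read_cohort, write_cohort
from ohca_partition.data_split import SplitSpec, random_split
from ohca_partition.pipeline import PRESETS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--split-seed", type=int, default=1)
    args = parser.parse_args()

    results = ROOT / "results"
    scratch = ROOT / "scratch"
    spec = SplitSpec(seed=args.split_seed)

    halves = {}
    manifest = {"split_seed": args.split_seed, "mode": spec.mode}
    for label, path in (("full", "analysis_cohort.csv"), ("rosc", "rosc_subgroup.csv")):
        cohort = read_cohort(scratch / path)
        derivation, validation = random_split(cohort, spec)
        halves[label] = (derivation, validation)
        write_cohort(derivation, scratch / f"derivation_{label}.csv")
        write_cohort(validation, scratch / f"validation_{label}.csv")
        manifest[label] = {
            "n": len(cohort),
            "derivation_n": len(derivation),
            "validation_n": len(validation),
        }
    (results / "split_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )

    for preset, (outcome, sequence, subgroup) in PRESETS.items():
        derivation, _ = halves["rosc" if subgroup else "full"]
        model = fit_ordered_partition(derivation, outcome, sequence)
        model.to_json(results / f"model_{preset}.json")
        (results / f"tree_{preset}.txt").write_text(
            model.render_text() + "\n", encoding="utf-8"
        )
        thresholds = ", ".join(
            f"{var} <= {cut} min" for var, cut in model.thresholds.items()
        )
        print(f"{preset:16s} (derivation n = {len(derivation):,}): {thresholds}")


if __name__ == "__main__":
    main()
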