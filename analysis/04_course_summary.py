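#!/usr/bin/env python
"""Course-level aggregation: summaries, reproducibility, clinical associations.

From the tidy MSE table of stage 02: per-session scale-band summaries,
per-condition means, the two-segment reproducibility correlation per region,
Pearson associations of the summaries with the catatonia score (BFCRS) and
serum BDNF — with and without the lorazepam sessions — and the recorded ECT
course statistics.  Writes results/summaries.csv and results/report.json.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from ectmse.course import (
    clinical_association,
    condition_average,
    ect_course_summary,
    reproducibility_correlation,
)
from ectmse.io import CONDITIONS, read_clinical_table, read_course_table
from ectmse.pipeline import _assoc_dict, curves_by_session, summaries_from_curves

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "scratch" / "study")
    ap.add_argument("--mse-csv", type=Path, default=ROOT / "results" / "mse.csv")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    df = pd.read_csv(args.mse_csv)
    clinical = read_clinical_table(args.study / "clinical.csv")
    conditions = {str(s): str(c) for s, c in clinical["condition"].items()}

    by_session = curves_by_session(df)
    summaries = summaries_from_curves(by_session, conditions)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        args.out_dir / "summaries.csv", index=False
    )

    report = {
        "condition_means": {c: condition_average(summaries, c) for c in CONDITIONS},
        "reproducibility_r": reproducibility_correlation(by_session),
        "associations": {
            "all_conditions": _assoc_dict(
                clinical_association(summaries, clinical, on_insufficient="skip")
            ),
            "lorazepam_excluded": _assoc_dict(
                clinical_association(
                    summaries, clinical, exclude=("lorazepam",), on_insufficient="skip"
                )
            ),
        },
        "ect_course": ect_course_summary(read_course_table(args.study / "course.csv")),
    }
    with open(args.out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)

    print("two-segment reproducibility r per region:")
    for region, r in report["reproducibility_r"].items():
        print(f"  {region:<10} {r:+.3f}")
    print("\nBFCRS association (frontocentral fine-scale summary):")
    for key in ("all_conditions", "lorazepam_excluded"):
        entry = report["associations"][key].get("frontocentral_low_sf__vs__bfcrs")
        if entry:
            print(f"  {key:<20} r = {entry['pearson_r']:+.3f} (n={entry['n_points']})")
    ect = report["ect_course"]
    print(
        f"\nECT course: threshold {ect['threshold_first_mC']} mC, "
        f"mean charge {ect['mean_charge_mC']:.1f} mC, "
        f"mean seizure {ect['mean_seizure_s']:.2f} s, "
        f"{ect['n_failed']} failed stimulation(s)"
    )
    print(f"\nreport -> {args.out_dir / 'report.json'}")


if __name__ == "__main__":
    main()
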