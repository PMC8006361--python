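"""The five-location statistical comparison.

Reads the segment table from step 02 and runs the full battery: group
medians, Friedman + Dunn-Bonferroni contrasts across locations,
regression and Bland-Altman agreement against the basal-LV reference,
ROC with Youden cutoffs, paired DeLong AUC comparisons, intraclass
correlation, and per-patient ischemic burden at the aortic-root cutoffs.

Usage: python analysis/03_location_statistics.py
"""

import json
from pathlib import Path

import pandas as pd

from cmrperf.stats import run_location_comparison

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = RESULTS / "segment_table.csv"
    if not path.exists():
        raise SystemExit("segment table not found: run analysis/02_quantify_segments.py first")
    table = pd.read_csv(path)
    report = run_location_comparison(table)

    # agreement table (regression + Bland-Altman vs bLV)
    rows = []
    for (metric, loc), a in report.agreement.items():
        rows.append(
            {
                "metric": metric,
                "location": loc,
                "slope": round(a.slope, 3),
                "slope_ci_lo": round(a.slope_ci[0], 3),
                "slope_ci_hi": round(a.slope_ci[1], 3),
                "r_squared": round(a.r_squared, 3),
                "bias": round(a.bias, 3),
                "loa_half_width": round(a.loa_half_width, 3),
            }
        )
    pd.DataFrame(rows).to_csv(RESULTS / "agreement_vs_blv.csv", index=False)

    # diagnostic-accuracy table (ROC per metric and location)
    rows = []
    for (metric, loc), r in report.roc.items():
        rows.append(
            {
                "metric": metric,
                "location": loc,
                "auc": round(r.auc, 3),
                "auc_ci_lo": round(r.auc_ci[0], 3),
                "auc_ci_hi": round(r.auc_ci[1], 3),
                "sensitivity_pct": round(100 * r.sensitivity),
                "specificity_pct": round(100 * r.specificity),
                "cutoff": round(r.cutoff, 2),
            }
        )
    pd.DataFrame(rows).to_csv(RESULTS / "diagnostic_accuracy.csv", index=False)

    (RESULTS / "location_report.json").write_text(
        json.dumps(report.to_json_dict(), indent=1, default=float)
    )

    print("ROC summary (abnormal = positive, value <= cutoff -> positive):")
    print(pd.DataFrame(rows).to_string(index=False))
    print("\nFriedman p-values:")
    for (metric, label), (stat, p) in report.friedman.items():
        print(f"  {metric} / {label}: chi2={stat:.1f}, p={p:.2e}")
    print("\nICC of stress MBF by patient:", {k: round(v, 2) for k, v in report.icc.items()})


if __name__ == "__main__":
    main()
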