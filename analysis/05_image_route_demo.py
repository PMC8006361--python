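"""Image-space demonstration on one rendered patient.

Renders a single patient of the calibrated cohort to signal space
(annular LV phantom + 3-chamber AIF plane) and runs the full inverse
chain — coil correction, saturation-recovery inversion, ROI AIF
extraction, pixel-wise Fermi deconvolution, polar/AHA mapping — once
with the basal-LV AIF and once with the aortic-root AIF. The same
imaging data yield systematically higher MBF for the bLV sampling
site; the AoR estimate is compared against the known ground truth.
NIfTI volumes go to scratch/ (bulky), the summary to results/.

Usage: python analysis/05_image_route_demo.py [--seed N]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from cmrperf.io import write_rendered_patient
from cmrperf.pipeline import image_route_segment_mbf
from cmrperf.render import render_patient
from cmrperf.synthetic import StudyConfig, simulate_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=3)
    args = ap.parse_args()

    cfg = StudyConfig(n_patients=1, seed=args.seed)
    study = simulate_study(cfg)
    pat = study.patients[0]
    rendered = render_patient(pat, cfg, "stress")
    write_rendered_patient(rendered, ROOT / "scratch" / "rendered_patient")

    summary = {}
    for loc in ("bLV", "AoR"):
        seg = image_route_segment_mbf(rendered, loc)
        rel = np.abs(seg - pat.true_stress_mbf) / pat.true_stress_mbf
        summary[loc] = {
            "mean_stress_mbf": float(np.mean(seg)),
            "max_segment_rel_error_vs_truth": float(rel.max()),
        }
        print(f"{loc}: mean stress MBF {np.mean(seg):.2f} mL/g/min "
              f"(max deviation from true MBF {100 * rel.max():.1f}%)")
    ratio = summary["bLV"]["mean_stress_mbf"] / summary["AoR"]["mean_stress_mbf"]
    summary["blv_over_aor_mean_ratio"] = ratio
    print(f"bLV/AoR mean MBF ratio on identical images: {ratio:.2f}")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    (out / "image_route_summary.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
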