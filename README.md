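# cmrperf

Quantitative first-pass stress/rest cardiac MR perfusion analysis, built
around one clinical question: **where should the arterial input function
(AIF) be sampled?** Absolute myocardial blood flow (MBF) from
dynamic contrast-enhanced CMR is obtained by deconvolving each tissue
enhancement curve against an AIF measured in a blood pool. The
conventional choice is the basal left-ventricular (bLV) cavity, but a
dual-sequence acquisition also images the left atrium (LA), mid and
apical LV (mLV, aLV) and the aortic root (AoR). Because partial-volume
and mixing effects depress the measured arterial concentration inside
the LV, and deconvolution is linear in the AIF, LV-sampled AIFs inflate
MBF — and patient-to-patient variability of that inflation degrades the
diagnostic accuracy of stress MBF for detecting abnormal perfusion,
while the stress/rest ratio (MPR) is largely protected.

The package provides, for researchers in perfusion quantification:

- **`cmrperf.synthetic`** — a seeded generator of complete synthetic
  stress/rest studies: gamma-variate bolus with recirculation,
  location-specific AIF distortion, tissue curves from forward Fermi
  convolution at known MBF, 25 patients x 16 AHA segments with a 75/25
  normal/abnormal split, and optional rendering to image space
  (`cmrperf.render`).
- **`cmrperf.signal_model`** — saturation-recovery signal <-> gadolinium
  conversion (`S = scale (1 - e^{-TS R1})`, `R1 = 1/T1_0 + r1 C`) and
  proton-density coil correction.
- **`cmrperf.curves`** — ROI extraction, shape-preserving temporal
  interpolation, triangle-method bolus-arrival detection, first/second
  pass separation, and the 20-s minimum deconvolution window.
- **`cmrperf.fermi`** — Fermi-function-constrained deconvolution
  `h(t) = F / (1 + e^{(t - Δ - T0)/W})` for `t >= Δ` with delay search,
  and `MBF = h(Δ) · 60 / 1.05` (mL/g/min); pixel-wise maps inside a
  12 x 12 cm² LV bounding box.
- **`cmrperf.segments`** — 60 x 10 polar resampling between manual
  contours and AHA 16-segment averaging; MPR.
- **`cmrperf.stats`** — Friedman/Dunn-Bonferroni contrasts, regression
  and Bland-Altman agreement against bLV, ROC with Youden cutoffs
  (inclusive rule: value <= cutoff calls a segment abnormal), paired
  DeLong AUC comparisons, one-way ICC and ischemic burden.

## Worked example

```python
from cmrperf.pipeline import quantify_study
from cmrperf.stats import roc_analysis
from cmrperf.synthetic import StudyConfig, simulate_study

study = simulate_study(StudyConfig(seed=3))          # 25 patients, 400 segments
table = quantify_study(study, locations=("bLV", "AoR"))
for loc in ("bLV", "AoR"):
    sub = table[table.location == loc]
    r = roc_analysis(sub["stress_mbf"].to_numpy(), sub["label"].to_numpy())
    print(loc, f"AUC {r.auc:.3f}  cutoff {r.cutoff:.2f}  "
               f"sens {r.sensitivity:.2f}  spec {r.specificity:.2f}")
```

prints

```
bLV AUC 0.808  cutoff 2.30  sens 0.75  spec 0.76
AoR AUC 0.897  cutoff 2.02  sens 0.78  spec 0.88
```

i.e. on this seed the aortic-root AIF classifies abnormal segments more
accurately than the basal-LV reference (AUC 0.90 vs 0.81), and its
optimal stress-MBF cutoff (2.02 mL/g/min) sits well below the bLV one
(2.30) — ischemia thresholds are not transferable between sampling
locations. Single-cohort AUC estimates carry sampling noise of a few
hundredths; `analysis/04_replicate_aucs.py` quantifies how stable the
ordering is across 50 regenerated cohorts.

The numbered scripts under `analysis/` run the full study in order:
`01_simulate_study.py` (cohort + ground truth), `02_quantify_segments.py`
(segment table for all five locations), `03_location_statistics.py`
(agreement, ROC and DeLong tables), `04_replicate_aucs.py` (50-replicate
AUC ordering experiment) and `05_image_route_demo.py` (rendered
image-space pipeline on one patient). Outputs land in `results/`.

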