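# Methods

## Problem and model

First-pass perfusion CMR measures the transit of a gadolinium bolus
through the myocardium. Under linear, stationary tracer kinetics the
tissue concentration is the convolution of the arterial input function
(AIF) with a tissue impulse response,

    C_t(t) = ∫ C_a(τ) · h(t − τ) dτ,

and the initial height of `h` equals blood flow (central volume
principle). The package constrains `h` to a delayed Fermi function

    h(t) = F / (1 + exp((t − Δ − T0) / W)),  t ≥ Δ;  h = 0 for t < Δ,

with amplitude `F` (s⁻¹), shoulder `T0` (s), decay width `W` (s) and a
unit-step contrast-arrival delay `Δ` (s). The flow readout is the
plateau at arrival converted to clinical units:

    MBF = h(Δ) · 60 / ρ,  ρ = 1.05 g/mL.

MPR is the stress/rest ratio of segmental MBF.

Deconvolution is linear in the AIF: scaling `C_a` by `k` scales every
fitted MBF by `1/k`. This is the mechanism by which the choice of AIF
sampling location (LA, bLV, mLV, aLV, AoR) propagates into MBF, MPR,
ROC cutoffs and ischemic-burden estimates.

## Numerical formulation of the deconvolution

Curves are resampled to a uniform grid (default dt = 0.5 s; the source
frame rate is one RR interval) with PCHIP, which preserves knot values
and introduces no new extrema. The discrete model is a **trapezoidal**
convolution of the AIF with the zero-delay kernel followed by a time
shift of `Δ` (linear interpolation for fractional shifts). The
trapezoidal rule matters: a left-endpoint Riemann sum at dt = 0.5 s
deviates from the continuous integral enough to bias MBF by several
percent when fitting curves that originate at a finer resolution. The
synthetic generator uses the identical discrete model, so on-grid
refits are exact to machine precision.

For fixed `(Δ, T0, W)` the model is linear in `F`, whose least-squares
value has a closed form (projected onto `(0, F_max]`, `F_max` = 1 s⁻¹ ≈
57 mL/g/min). The nonlinear search therefore runs over `(T0, W)` only:
a deterministic 9 × 7 coarse grid (`T0` linear on [0, window], `W`
geometric on [dt/2, window]) whose convolutions are shared across all
candidate delays via the shift structure, followed by a bounded
Nelder–Mead polish. There is no randomness anywhere in the fit; maps
are bit-reproducible.

**Delay search.** The initial delay is the difference between the
tissue and AIF upslope-start times (≥ 0). The fit is repeated at every
grid delay within ±3 s of that estimate (step dt, clamped at zero), and
the smallest-SSE delay wins, ties to the smaller delay. Because true
contrast arrival is not a multiple of dt, the three best grid delays
are then polished in a continuous `(Δ, T0, W)` refinement (each within
±dt of its grid value). Without this refinement, delay quantization
lets the shallow (T0, W) valley absorb the onset mismatch and biases
the plateau readout by up to ~8% on noiseless curves; with it the
worst-case noiseless error is ~0.4%.

**Windowing.** All curves are cropped to [AIF upslope start, first/
second-pass split]; windows shorter than 20 s are extended at washout
to exactly 20 s (or to the end of the acquisition, with a warning).
Baselines (mean of pre-onset samples, minimum 2) are subtracted after
landmark detection. Negative concentration samples from noise are
retained to avoid rectification bias.

**Landmarks.** Bolus arrival uses the triangle method on the segment
from the first sample to the first-pass peak, normalized to the chord
span so detection is invariant to amplitude scaling. The literal
chord-distance argmax lies on the rising flank, biased late by up to
~0.8 s on smooth boluses, so the implementation adds sub-sample
parabolic localization of the distance maximum and projects the local
tangent back to the baseline level; this is exact for a piecewise-linear
rise and keeps onset errors below ±0.4 s across onsets in [3, 20] s.
Pass separation smooths with a 3-sample moving average, finds
first-derivative sign-change maxima with prominence ≥ 10% of the
first-pass amplitude, and splits at the curve minimum strictly between
the two most prominent peaks; a single-peak curve has no split and the
window runs to the last sample.

## Signal model

Signals follow the idealized saturation-recovery relation
`S = scale · (1 − exp(−TS · R1))` with `R1 = 1/T1₀ + r1 · C`,
TS = 23.5 ms on the low-resolution AIF plane and 100 ms on the
myocardial planes, and gadobutrol relaxivity r1 = 5.0 L mmol⁻¹ s⁻¹ at
3 T (configurable). The spoiled-gradient-echo readout train and water
exchange are not modelled: the relation captures the saturation
nonlinearity that must be corrected before deconvolution, and it
inverts in closed form. The per-pixel `scale` is calibrated from ≥ 2
pre-contrast frames and the native T1 map, which also absorbs any
smooth coil-sensitivity profile; proton-density division (smoothed,
max-normalized, floor-masked) is still applied first, as in the
acquisition protocol. Note the nonlinearity is substantial at
first-pass arterial concentrations even on the short-TS plane: at
8 mM the signal falls ~35% below the linear-in-R1 approximation
(relative shortfall ≈ TS·R1/2), which is exactly why the conversion is
required; the linear regime (< 5% deviation) ends near 0.7 mM.

## Segmental mapping

Pixel-wise MBF inside a 12 × 12 cm² LV-centered box is resampled onto a
polar grid of 60 angular positions (6° sectors anchored at the superior
RV insertion, counterclockwise in the standard short-axis display) and
10 transmural layers (endo → epi, cell centers at depths (k − 0.5)/10).
Cells sample bilinearly at their centers, restricted to pixels between
the contours — without that restriction, cavity pixels (which fit at
absurdly high MBF) bleed into the subendocardial layer. Empty cells
inherit the nearest valid angular neighbor and are flagged. The AHA
reduction averages 10 positions × 10 layers per basal/mid segment and
15 × 10 per apical segment (segments 1–6 basal, 7–12 mid, 13–16 apical;
no apical cap). MPR divides stress by rest per (patient, segment,
location); rest values below 0.05 mL/g/min give a flagged, undefined
MPR.

## Synthetic-study generator

The generator defines the study conditions; all defaults below are
fixed, seeded, and reproduced bit-for-bit from the configuration.

- **Cohort**: 25 patients × 16 segments; exactly
  round(0.25 · 400) = 100 abnormal segments, packed into 12 diseased
  patients (disease clusters within patients; this also produces a
  realistic intraclass correlation).
- **True MBF**: two-piece lognormal per label, matched to the median
  and *both* quartiles separately. Stress: 2.42 (2.15–2.84) mL/g/min
  normal, 1.71 (1.28–1.98) abnormal — the aortic-root segmental values
  of the motivating clinical cohort. The abnormal quartiles are
  markedly left-skewed; honoring that asymmetry matters, since a
  symmetric lognormal with the same IQR understates the separation
  between the groups (implied reference-location AUC ~0.81 instead of
  the observed ~0.90). Rest: normal 1.00 (0.85–1.20), abnormal 0.96
  (0.85–1.21), so MPR medians come out near 2.4 (normal) and 1.8
  (abnormal). A patient-level log-normal effect (σ = 0.12) is shared
  between phases; segment-level spread makes up the remainder of the
  configured quartiles.
- **Bolus**: peak-normalized gamma variate `A u^α e^{α(1−u)}`,
  `u = (t − t₀)/(αβ)`, A = 6 mM stress / 5 mM rest, onset 5 s, α = 3,
  β = 1.5 s, plus recirculation: the first-pass term delayed 20 s,
  scaled 0.25, time-stretched 1.8.
- **Location effects** (relative to the AoR reference): amplitude
  factors LA 0.917, bLV 0.871, mLV 0.849, aLV 0.823 (chosen so measured
  bLV/AoR MBF ≈ 2.78/2.42 in normal segments and the LV sites read
  high); Gaussian dispersion 0.2–0.7 s; arrival shifts −1.0 … 0 s
  (LA fills first); AIF sample noise 0.05 mM. Amplitude variability has
  two log-normal components per site: a **patient-shared jitter**
  (σ: LA 0.17, bLV 0.24, mLV 0.36, aLV 0.31, AoR 0), identical in a
  patient's stress and rest scans (anatomy-driven partial volume), and
  a smaller **per-scan jitter** (σ: 0.06, 0.08, 0.30, 0.08, 0)
  capturing breath-hold and ROI-placement differences between scans.
  Deterministic scaling alone is rank-invariant and cannot change an
  AUC; patient-level variability is what degrades stress-MBF accuracy
  at LV sites. The shared part cancels in MPR; the per-scan part does
  not, which is why the mid-LV — the site with the largest scan-to-scan
  variability — loses accuracy for MPR as well. The σ values are
  calibrated so the simulated per-location AUCs reproduce the clinical
  ones (stress ≈ 0.83/0.81/0.71/0.78 at LA/bLV/mLV/aLV vs 0.90 at AoR;
  MPR ≈ 0.82/0.81/0.69/0.80 vs 0.83).
- **Kinetics**: Fermi kernel T0 = 20 s, W = 4 s; tissue arrival delays
  uniform on [0.5, 2.5] s; tissue noise 0.05 mM (≈ SNR 20–30 at
  stress). Frame times jitter by RR ± 5% (RR = 0.9 s, 70 frames ≈ 63 s
  coverage) to exercise temporal interpolation.
- **Rendering** (optional): concentric-annulus LV (endo 18 mm,
  epi 28 mm) on a 128 × 128 grid at 1.3 mm, per-segment wedges, a
  3-chamber plane with five 7-mm blood pools carrying the distorted
  AIFs, smooth coil shading, proton-density pairs and T1 maps
  (blood 1.6 s, myocardium 1.2 s).

What the generator does **not** emulate: respiratory/cardiac motion,
dark-rim artefacts, realistic coil geometry, spatially varying
myocardial kinetics within a segment, and model mismatch between the
true tissue response and the Fermi family. Passing tests therefore
demonstrate internal consistency of the pipeline and the plausibility
of the location-effect mechanism — not performance on clinical data.

## Statistics

Group summaries are always median (IQR). Friedman's two-way ANOVA by
ranks (tie-corrected, χ² with k − 1 df) compares the five locations
within each label group, with Dunn post-hoc z-tests on the Friedman
mean ranks, Bonferroni-corrected over the C = 10 location pairs.
Agreement against the bLV reference uses OLS (slope with t-based 95%
CI, R²) and Bland–Altman (bias = mean(other − bLV); positive bias means
overestimation relative to bLV; limits ± 1.96 SD). ROC analysis fixes
abnormal as the positive class with low values positive; AUC is the
tie-aware Mann–Whitney statistic with a DeLong-variance normal CI; the
Youden cutoff is searched over observed values under the inclusive rule
(value ≤ cutoff → positive), ties broken toward higher specificity, so
the reported cutoff is an attainable datum. Paired DeLong tests use
placement-value covariances; families: 10 location pairs per metric,
plus 5 same-location stress-vs-MPR comparisons. Segments are treated
as independent in ROC comparisons; the one-way ICC(1,1) of stress MBF
clustered by patient is reported alongside so the clustering magnitude
is visible. Ischemic burden is the percentage of a patient's 16
segments at or below a fixed (AoR-derived) cutoff.

## Problem sizes and runtime choices

Cohort-scale experiments use segment-level fitting (the per-segment
tissue curves are deconvolved directly); pixel-wise fitting with polar
and AHA reduction is exercised on rendered single patients, where the
noiseless image-route pipeline recovers true segmental MBF within 2%.
The replicate experiment regenerates the cohort 50 times with derived
seeds, quantifying the bLV and AoR on every replicate and all five
locations on every fifth. These sizes keep the full analysis suite in
the minutes range on one CPU while leaving every stage of the method
exercised at the clinical dimensions (400 segments, 5 locations, 2
phases).

## Known limitations

- The Fermi family is both the generator and the fitted model; real
  myocardium violates it, and the recovery numbers here bound only the
  numerical, not the physiological, error.
- The saturation-recovery relation ignores the readout train; absolute
  concentration scales are therefore idealized (consistently in forward
  and inverse directions).
- DeLong comparisons ignore intra-patient clustering (ICC is reported,
  not corrected for).
- The polar resampling uses single-point bilinear sampling per cell;
  mean conservation against in-wall pixels is ~1–2% on smooth maps and
  worse across sharp wedge boundaries.
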