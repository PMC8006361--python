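"""Synthetic stress/rest perfusion studies with known ground truth.

The generator emulates the data structure of a dual-sequence stress/rest
perfusion study: 25 patients x 16 AHA segments with a 75%/25%
normal/abnormal split, a gamma-variate contrast bolus with
recirculation, location-specific distortion of the arterial input
function (AIF) at the five sampling sites (LA, bLV, mLV, aLV, AoR), and
tissue curves produced by forward convolution with the same Fermi kernel
the quantification stage fits. Everything downstream is therefore
testable against exact ground truth.

The central mechanism under study is encoded in the location effects:
sites inside the LV cavity see systematically *lower* gadolinium
concentration (partial volume, incomplete mixing, systolic motion),
which — by the linearity of deconvolution — inflates the measured MBF.
A per-patient amplitude jitter at those sites, shared between the
stress and rest scans of a patient (it is anatomy-driven), widens the
measured-MBF distributions and thereby degrades diagnostic accuracy for
stress MBF while largely cancelling in the stress/rest ratio (MPR),
reproducing the qualitative behaviour of the five locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cmrperf.curves import ConcentrationCurve
from cmrperf.fermi import MYOCARDIAL_DENSITY
from cmrperf.imagedata import AIF_LOCATIONS

__all__ = [
    "BolusParams",
    "LocationEffect",
    "StudyConfig",
    "PatientStudy",
    "SyntheticStudy",
    "gamma_variate_aif",
    "make_location_family",
    "simulate_tissue_curve",
    "simulate_study",
    "default_location_effects",
    "fermi_amplitude_for_mbf",
]

_Z_IQR = 2.0 * 0.6744897501960817  # IQR width in units of sigma for a normal


def _sigma_from_iqr(q1: float, q3: float) -> float:
    """Log-normal sigma implied by a median-centered (q1, q3) pair."""
    return float(np.log(q3 / q1) / _Z_IQR)


@dataclass(frozen=True)
class BolusParams:
    """Gamma-variate first-pass bolus with a delayed recirculation copy.

    The first pass is peak-normalized: C(t) = A u^alpha exp(alpha(1-u))
    with u = (t - onset)/(alpha beta), so the maximum is exactly
    ``peak_amplitude`` at t = onset + alpha*beta. Recirculation is the
    first-pass term delayed by ``recirc_delay``, scaled by
    ``recirc_fraction`` and time-stretched by ``recirc_broadening``.
    """

    peak_amplitude: float = 6.0  # mM
    onset_time: float = 5.0  # s
    alpha: float = 3.0
    beta: float = 1.5  # s
    recirc_delay: float = 20.0  # s
    recirc_fraction: float = 0.25
    recirc_broadening: float = 1.8

    def __post_init__(self) -> None:
        if self.peak_amplitude <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("peak_amplitude, alpha and beta must be positive")
        if not 0 <= self.recirc_fraction < 1:
            raise ValueError("recirc_fraction must be in [0, 1)")
        if self.recirc_broadening < 1:
            raise ValueError("recirc_broadening must be >= 1")


@dataclass(frozen=True)
class LocationEffect:
    """Distortion applied to the true bolus at one AIF sampling site.

    ``amplitude_factor`` scales the whole curve (partial-volume signal
    loss), ``dispersion_s`` is the SD of a unit-mass Gaussian smoothing
    kernel, ``delay_shift_s`` shifts the curve in time, ``noise_sd`` is
    per-sample measurement noise. Amplitude variability has two
    log-normal components: ``amplitude_jitter_sd``, drawn once per
    patient and shared between the stress and rest scans (anatomy-driven
    partial volume: trabeculation, papillary muscles), and
    ``amplitude_jitter_scan_sd``, drawn independently per scan
    (breath-hold position, heart rate, ROI placement). The shared part
    cancels in the stress/rest ratio; the per-scan part does not.
    """

    location: str
    amplitude_factor: float = 1.0
    dispersion_s: float = 0.0
    delay_shift_s: float = 0.0
    noise_sd: float = 0.0
    amplitude_jitter_sd: float = 0.0
    amplitude_jitter_scan_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.location not in AIF_LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.amplitude_factor <= 0:
            raise ValueError("amplitude_factor must be positive")
        if (
            self.dispersion_s < 0
            or self.noise_sd < 0
            or self.amplitude_jitter_sd < 0
            or self.amplitude_jitter_scan_sd < 0
        ):
            raise ValueError("dispersion, noise and jitter must be >= 0")


def default_location_effects() -> dict[str, LocationEffect]:
    """Per-site distortions reproducing the clinical ordering of effects.

    The aortic root is the undistorted reference. Amplitude factors are
    set so the measured-MBF medians across sites keep the observed
    ordering (LV sites read high, the basal-LV/aortic-root ratio is
    about 2.78/2.42); jitter is largest at the mid/apical LV where
    systolic motion and trabeculation hit hardest.
    """
    return {
        "LA": LocationEffect("LA", 0.917, 0.2, -1.0, 0.05, 0.17, 0.06),
        "bLV": LocationEffect("bLV", 0.871, 0.3, -0.6, 0.05, 0.24, 0.08),
        "mLV": LocationEffect("mLV", 0.849, 0.5, -0.4, 0.05, 0.36, 0.30),
        "aLV": LocationEffect("aLV", 0.823, 0.7, -0.2, 0.05, 0.31, 0.08),
        "AoR": LocationEffect("AoR", 1.0, 0.0, 0.0, 0.05, 0.0, 0.0),
    }


def identity_location_effects(noise_sd: float = 0.0) -> dict[str, LocationEffect]:
    """All five sites read the true bolus (null configuration)."""
    return {loc: LocationEffect(loc, noise_sd=noise_sd) for loc in AIF_LOCATIONS}


def _gamma_variate(t: np.ndarray, amp: float, onset: float, alpha: float, beta: float) -> np.ndarray:
    u = (t - onset) / (alpha * beta)
    out = np.zeros_like(t, dtype=float)
    pos = u > 0
    out[pos] = amp * u[pos] ** alpha * np.exp(alpha * (1.0 - u[pos]))
    return out


def gamma_variate_aif(params: BolusParams, times: np.ndarray) -> ConcentrationCurve:
    """Evaluate the bolus model (first pass + recirculation) on a grid."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be 1-D and strictly increasing")
    c = _gamma_variate(times, params.peak_amplitude, params.onset_time, params.alpha, params.beta)
    if params.recirc_fraction > 0:
        c = c + _gamma_variate(
            times,
            params.peak_amplitude * params.recirc_fraction,
            params.onset_time + params.recirc_delay,
            params.alpha,
            params.beta * params.recirc_broadening,
        )
    return ConcentrationCurve(times, c)


def apply_location_effect(
    curve: ConcentrationCurve,
    effect: LocationEffect,
    rng: np.random.Generator | None = None,
    amplitude_jitter: float = 1.0,
) -> ConcentrationCurve:
    """Scale, disperse, shift and noise a true bolus for one site."""
    dt = curve.dt  # raises on non-uniform grids
    v = curve.values * effect.amplitude_factor * amplitude_jitter
    if effect.dispersion_s > 0:
        half = int(np.ceil(4 * effect.dispersion_s / dt))
        kt = np.arange(-half, half + 1) * dt
        kernel = np.exp(-0.5 * (kt / effect.dispersion_s) ** 2)
        kernel /= kernel.sum()  # unit mass: preserves the area under the curve
        v = np.convolve(np.pad(v, half, mode="edge"), kernel, mode="valid")
    if effect.delay_shift_s != 0.0:
        v = np.interp(curve.times - effect.delay_shift_s, curve.times, v, left=v[0], right=v[-1])
    if effect.noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        v = v + rng.normal(0.0, effect.noise_sd, size=v.shape)
    return ConcentrationCurve(curve.times.copy(), v)


def make_location_family(
    base: BolusParams | ConcentrationCurve,
    effects: dict[str, LocationEffect],
    times: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    amplitude_jitter: dict[str, float] | None = None,
) -> dict[str, ConcentrationCurve]:
    """The five per-site AIFs derived from one true bolus.

    ``base`` may be bolus parameters (evaluated on ``times``) or an
    already-sampled true curve. An identity effect returns the base
    curve unchanged, so the AoR output equals the truth by default.
    """
    missing = set(AIF_LOCATIONS) - set(effects)
    if missing:
        raise ValueError(f"missing location effects: {sorted(missing)}")
    if isinstance(base, BolusParams):
        if times is None:
            raise ValueError("times required when base is BolusParams")
        base_curve = gamma_variate_aif(base, times)
    else:
        base_curve = base
    out = {}
    for loc in AIF_LOCATIONS:
        jit = 1.0 if amplitude_jitter is None else amplitude_jitter.get(loc, 1.0)
        out[loc] = apply_location_effect(base_curve, effects[loc], rng, jit)
    return out


def fermi_amplitude_for_mbf(mbf: float, t0: float, w: float) -> float:
    """F_amp such that the response plateau h(delay) reads out ``mbf``."""
    return mbf * MYOCARDIAL_DENSITY / 60.0 * (1.0 + np.exp(-t0 / w))


def simulate_tissue_curve(
    aif: ConcentrationCurve,
    mbf: float,
    fermi_shape: tuple[float, float] = (20.0, 4.0),
    delay: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ConcentrationCurve:
    """Forward model: tissue curve = AIF convolved with a Fermi kernel.

    The kernel is the same delayed Fermi response the quantification
    stage fits, with amplitude chosen so its MBF readout equals ``mbf``;
    the convolution is the discrete Riemann sum on the AIF grid.
    """
    if mbf < 0:
        raise ValueError("mbf must be >= 0")
    t0, w = fermi_shape
    if w <= 0:
        raise ValueError("Fermi decay width W must be positive")
    dt = aif.dt  # raises if not uniform
    t_rel = aif.times - aif.times[0]
    if mbf == 0:
        v = np.zeros_like(t_rel)
    else:
        from cmrperf.fermi import FermiFit, fermi_response

        f_amp = fermi_amplitude_for_mbf(mbf, t0, w)
        h0 = fermi_response(t_rel, FermiFit(f_amp, t0, w, 0.0, 0.0))
        n = len(t_rel)
        a = aif.values
        # trapezoidal discrete convolution with the zero-delay kernel
        # (endpoint samples half-weighted, so the quadrature tracks the
        # continuous integral over the kernel support), then a time shift
        # by the contrast-arrival delay — the same discrete model the
        # deconvolution stage fits
        m0 = dt * (np.convolve(a, h0)[:n] - 0.5 * (a[0] * h0[:n] + h0[0] * a[:n]))
        v = np.interp(t_rel - delay, t_rel, m0, left=0.0)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return ConcentrationCurve(aif.times.copy(), v)


@dataclass
class StudyConfig:
    """Study conditions for the synthetic cohort.

    Label-dependent true MBF is log-normal; the medians and IQRs default
    to the aortic-root segmental values of a stress/rest cohort of 25
    patients (normal stress 2.42 (2.15-2.84), abnormal 1.71 (1.28-1.98)
    mL/g/min), with a patient-level random effect shared between phases.
    """

    n_patients: int = 25
    segments_per_patient: int = 16
    abnormal_prevalence: float = 0.25
    n_diseased_patients: int = 12

    stress_median_normal: float = 2.42
    stress_iqr_normal: tuple[float, float] = (2.15, 2.84)
    stress_median_abnormal: float = 1.71
    stress_iqr_abnormal: tuple[float, float] = (1.28, 1.98)
    rest_median_normal: float = 1.00
    rest_iqr_normal: tuple[float, float] = (0.85, 1.20)
    rest_median_abnormal: float = 0.96
    rest_iqr_abnormal: tuple[float, float] = (0.85, 1.21)
    patient_effect_sd: float = 0.12  # log scale, shared stress/rest

    rr_interval_s: float = 0.9
    rr_jitter_frac: float = 0.05
    n_frames: int = 70

    stress_bolus: BolusParams = field(default_factory=BolusParams)
    rest_bolus: BolusParams = field(default_factory=lambda: BolusParams(peak_amplitude=5.0))
    location_effects: dict[str, LocationEffect] = field(default_factory=default_location_effects)

    fermi_t0_s: float = 20.0
    fermi_w_s: float = 4.0
    tissue_delay_range_s: tuple[float, float] = (0.5, 2.5)
    tissue_noise_sd: float = 0.05  # mM

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.abnormal_prevalence <= 1:
            raise ValueError("abnormal_prevalence must be in [0, 1]")
        if self.n_patients < 1 or self.segments_per_patient < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.n_frames * self.rr_interval_s < 50.0:
            raise ValueError("acquisition must cover at least 50 s")

    def sigma_segment(self, phase: str, label: str) -> tuple[float, float]:
        """Segment-level (lower, upper) log-SDs after removing the
        patient effect.

        The label distributions are two-piece lognormals matched to the
        configured median and both quartiles separately — the clinical
        quartiles are markedly asymmetric (abnormal stress MBF has a
        long lower tail), and a symmetric fit understates the
        separation between the groups.
        """
        q1, q3 = {
            ("stress", "normal"): self.stress_iqr_normal,
            ("stress", "abnormal"): self.stress_iqr_abnormal,
            ("rest", "normal"): self.rest_iqr_normal,
            ("rest", "abnormal"): self.rest_iqr_abnormal,
        }[(phase, label)]
        med = {
            ("stress", "normal"): self.stress_median_normal,
            ("stress", "abnormal"): self.stress_median_abnormal,
            ("rest", "normal"): self.rest_median_normal,
            ("rest", "abnormal"): self.rest_median_abnormal,
        }[(phase, label)]
        z = 0.6744897501960817
        lo = np.log(med / q1) / z
        hi = np.log(q3 / med) / z
        strip = lambda s: float(  # noqa: E731
            np.sqrt(max(s**2 - self.patient_effect_sd**2, 1e-4))
        )
        return strip(lo), strip(hi)


@dataclass
class PatientStudy:
    """One patient's curves and ground truth."""

    patient_id: int
    frame_times: dict  # phase -> (n_frames,) jittered acquisition times
    base_aif: dict  # phase -> true noiseless ConcentrationCurve (frame grid)
    aifs: dict  # phase -> {location -> distorted ConcentrationCurve}
    tissue: dict  # phase -> list of segment ConcentrationCurve
    true_stress_mbf: np.ndarray
    true_rest_mbf: np.ndarray
    labels: np.ndarray  # 'normal' / 'abnormal'
    delays: dict  # phase -> (n_segments,) true contrast-arrival delays
    amp_jitter: dict  # phase -> {location -> realized amplitude factor}
    #: noise-free counterparts of ``aifs``/``tissue`` — measurement noise
    #: is a property of the signal, so image rendering starts from these
    #: and adds noise in signal space instead
    aifs_clean: dict = field(default_factory=dict)
    tissue_clean: dict = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    config: StudyConfig
    patients: list
    ground_truth: "object"  # pandas.DataFrame

    @property
    def n_segments(self) -> int:
        return len(self.ground_truth)


def _assign_labels(cfg: StudyConfig, rng: np.random.Generator) -> np.ndarray:
    """Exact stratified labels, clustered into a subset of patients.

    Exactly round(prevalence * n_total) segments are abnormal; they are
    packed into ``n_diseased_patients`` randomly chosen patients (each
    taking at most all 16 of its segments), mirroring the clinical
    pattern where perfusion defects concentrate in diseased patients.
    """
    n_total = cfg.n_patients * cfg.segments_per_patient
    n_abn = int(round(cfg.abnormal_prevalence * n_total))
    labels = np.full((cfg.n_patients, cfg.segments_per_patient), "normal", dtype=object)
    if n_abn == 0:
        return labels
    n_dis = min(max(cfg.n_diseased_patients, int(np.ceil(n_abn / cfg.segments_per_patient))), cfg.n_patients)
    diseased = rng.choice(cfg.n_patients, size=n_dis, replace=False)
    # spread the abnormal count over diseased patients as evenly as the
    # integer split allows, then randomize which segments are hit
    base, extra = divmod(n_abn, n_dis)
    counts = np.full(n_dis, base)
    counts[rng.choice(n_dis, size=extra, replace=False)] += 1
    counts = np.minimum(counts, cfg.segments_per_patient)
    short = n_abn - counts.sum()
    i = 0
    while short > 0:  # redistribute overflow from full patients
        if counts[i] < cfg.segments_per_patient:
            counts[i] += 1
            short -= 1
        i = (i + 1) % n_dis
    for p, c in zip(diseased, counts):
        segs = rng.choice(cfg.segments_per_patient, size=int(c), replace=False)
        labels[p, segs] = "abnormal"
    return labels


def _frame_grid(cfg: StudyConfig, rng: np.random.Generator) -> np.ndarray:
    rr = cfg.rr_interval_s * (
        1.0 + cfg.rr_jitter_frac * rng.uniform(-1.0, 1.0, size=cfg.n_frames - 1)
    )
    return np.concatenate([[0.0], np.cumsum(rr)])


def simulate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate a full stress/rest cohort with known ground truth.

    Curves are synthesized on a fine uniform grid (0.1 s) and then
    sampled at each patient's jittered RR frame times, so the pipeline's
    temporal interpolation is exercised realistically. The same seed
    reproduces the study bit for bit.
    """
    import pandas as pd

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    labels = _assign_labels(cfg, rng)

    dt_fine = 0.1
    t_fine = np.arange(0.0, cfg.n_frames * cfg.rr_interval_s * 1.1 + 5.0, dt_fine)

    med = {
        ("stress", "normal"): cfg.stress_median_normal,
        ("stress", "abnormal"): cfg.stress_median_abnormal,
        ("rest", "normal"): cfg.rest_median_normal,
        ("rest", "abnormal"): cfg.rest_median_abnormal,
    }

    patients = []
    records = []
    for pid in range(cfg.n_patients):
        patient_effect = rng.normal(0.0, cfg.patient_effect_sd)
        shared_jitter = {
            loc: float(np.exp(rng.normal(0.0, eff.amplitude_jitter_sd)))
            if eff.amplitude_jitter_sd > 0
            else 1.0
            for loc, eff in cfg.location_effects.items()
        }
        amp_jitter = {}
        for phase in ("stress", "rest"):
            amp_jitter[phase] = {
                loc: shared_jitter[loc]
                * (
                    float(np.exp(rng.normal(0.0, eff.amplitude_jitter_scan_sd)))
                    if eff.amplitude_jitter_scan_sd > 0
                    else 1.0
                )
                for loc, eff in cfg.location_effects.items()
            }
        frame_times = {}
        base_aif = {}
        aifs = {}
        aifs_clean = {}
        tissue = {}
        tissue_clean = {}
        delays = {}
        true_mbf = {}
        effects_clean = scale_effects(cfg.location_effects, noise_sd=0.0)
        for phase, bolus in (("stress", cfg.stress_bolus), ("rest", cfg.rest_bolus)):
            frames = _frame_grid(cfg, rng)
            frame_times[phase] = frames
            fine_base = gamma_variate_aif(bolus, t_fine)
            family_fine = make_location_family(
                fine_base, effects_clean, amplitude_jitter=amp_jitter[phase]
            )
            base_aif[phase] = ConcentrationCurve(
                frames, np.interp(frames, t_fine, fine_base.values)
            )
            aifs_clean[phase] = {
                loc: ConcentrationCurve(frames, np.interp(frames, t_fine, c.values))
                for loc, c in family_fine.items()
            }
            # measurement noise applied per acquired frame
            aifs[phase] = {}
            for loc, clean in aifs_clean[phase].items():
                sd = cfg.location_effects[loc].noise_sd
                v = clean.values
                if sd > 0:
                    v = v + rng.normal(0.0, sd, size=v.shape)
                aifs[phase][loc] = ConcentrationCurve(frames, v)
            mbf = np.empty(cfg.segments_per_patient)
            dls = rng.uniform(*cfg.tissue_delay_range_s, size=cfg.segments_per_patient)
            curves = []
            curves_clean = []
            for s in range(cfg.segments_per_patient):
                lab = labels[pid, s]
                sig_lo, sig_hi = cfg.sigma_segment(phase, lab)
                z = rng.normal()
                eps = z * (sig_lo if z < 0 else sig_hi)
                mbf[s] = med[(phase, lab)] * np.exp(patient_effect + eps)
                fine_tissue = simulate_tissue_curve(
                    fine_base,
                    mbf[s],
                    (cfg.fermi_t0_s, cfg.fermi_w_s),
                    delay=dls[s],
                    noise_sd=0.0,
                )
                v = np.interp(frames, t_fine, fine_tissue.values)
                curves_clean.append(ConcentrationCurve(frames, v.copy()))
                if cfg.tissue_noise_sd > 0:
                    v = v + rng.normal(0.0, cfg.tissue_noise_sd, size=v.shape)
                curves.append(ConcentrationCurve(frames, v))
            tissue[phase] = curves
            tissue_clean[phase] = curves_clean
            delays[phase] = dls
            true_mbf[phase] = mbf
        patients.append(
            PatientStudy(
                pid,
                frame_times,
                base_aif,
                aifs,
                tissue,
                true_mbf["stress"],
                true_mbf["rest"],
                labels[pid].copy(),
                delays,
                amp_jitter,
                aifs_clean,
                tissue_clean,
            )
        )
        for s in range(cfg.segments_per_patient):
            records.append(
                {
                    "patient": pid,
                    "segment": s + 1,
                    "label": labels[pid, s],
                    "true_stress_mbf": true_mbf["stress"][s],
                    "true_rest_mbf": true_mbf["rest"][s],
                    "true_mpr": true_mbf["stress"][s] / true_mbf["rest"][s],
                }
            )
    gt = pd.DataFrame.from_records(records)
    return SyntheticStudy(cfg, patients, gt)


def noiseless_config(**overrides) -> StudyConfig:
    """A convenience configuration with all noise sources off and
    identity location effects — used for exact-recovery checks."""
    cfg = StudyConfig(
        location_effects=identity_location_effects(),
        tissue_noise_sd=0.0,
        rr_jitter_frac=0.0,
        **overrides,
    )
    return cfg


def scale_effects(effects: dict[str, LocationEffect], **overrides) -> dict[str, LocationEffect]:
    """Copy a location-effect family with per-field overrides applied to all."""
    return {loc: replace(eff, **overrides) for loc, eff in effects.items()}
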