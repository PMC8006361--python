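"""Render a synthetic patient's curves into image space.

The phantom geometry is a concentric-annulus left ventricle on a
128 x 128 grid at 1.3 mm in-plane resolution (the reconstructed
resolution of the dual-sequence protocol): cavity blood inside an
18-mm endocardial radius, a 10-mm-thick myocardial wall split into AHA
wedges carrying the per-segment tissue curves, and a low-resolution
3-chamber plane holding five blood pools that carry the five
location-distorted AIFs. Proton-density images with a smooth
coil-shading field and pre-contrast T1 maps accompany each plane, so
the full inverse pipeline (coil correction, signal-to-concentration,
ROI extraction, deconvolution, polar mapping) can run end to end.
"""

from __future__ import annotations

import numpy as np

from cmrperf.curves import RoiSpec
from cmrperf.imagedata import AIF_LOCATIONS, DynamicSeries, T1Map
from cmrperf.segments import Contours
from cmrperf.signal_model import AcquisitionParams, concentration_to_signal
from cmrperf.synthetic import PatientStudy, StudyConfig

__all__ = ["render_patient", "PHANTOM_SHAPE", "PIXEL_SPACING_MM"]

PHANTOM_SHAPE = (128, 128)
PIXEL_SPACING_MM = 1.3
ENDO_RADIUS_MM = 18.0
EPI_RADIUS_MM = 28.0
BODY_RADIUS_MM = 60.0
T1_BLOOD = 1.6  # s, native
T1_MYO = 1.2
T1_BODY = 1.0
SIGNAL_SCALE = 1000.0

_SLICE_SEGMENTS = {"basal": (0, 6), "mid": (6, 6), "apical": (12, 4)}

_ROI_CENTERS_MM = {  # on the 3-chamber plane
    "LA": (45.0, 120.0),
    "bLV": (65.0, 95.0),
    "mLV": (85.0, 75.0),
    "aLV": (105.0, 55.0),
    "AoR": (120.0, 110.0),
}
_AIF_POOL_RADIUS_MM = 7.0


def _grid_mm(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    ys = np.arange(shape[0]) * PIXEL_SPACING_MM
    xs = np.arange(shape[1]) * PIXEL_SPACING_MM
    return np.meshgrid(xs, ys)  # (x, y), y indexes rows


def _shading(shape: tuple[int, int]) -> np.ndarray:
    """Smooth multiplicative coil-sensitivity surrogate."""
    xx, yy = _grid_mm(shape)
    w = shape[1] * PIXEL_SPACING_MM
    h = shape[0] * PIXEL_SPACING_MM
    return 0.7 + 0.5 * (xx / w) + 0.15 * (yy / h)


def render_patient(
    patient: PatientStudy,
    config: StudyConfig,
    phase: str = "stress",
    signal_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Produce image-space data for one patient and phase.

    Rendering starts from the patient's noise-free concentration curves
    — measurement noise is a property of the acquired signal, so it is
    added here in signal units (``signal_noise_sd``), not in
    concentration space (which would corrupt the pre-contrast baseline
    that calibrates the signal scale).

    Returns a dict with ``planes`` (DynamicSeries in signal units),
    ``pd`` (proton-density image pairs), ``t1`` (T1Map per plane),
    ``contours`` (per short-axis slice), ``rois`` (per AIF location) and
    ``lv_center`` in mm.
    """
    if signal_noise_sd > 0 and rng is None:
        rng = np.random.default_rng([config.seed, patient.patient_id, 7])
    frames = patient.frame_times[phase]
    ny, nx = PHANTOM_SHAPE
    xx, yy = _grid_mm(PHANTOM_SHAPE)
    cx = cy = (PHANTOM_SHAPE[0] // 2) * PIXEL_SPACING_MM
    rr = np.hypot(xx - cx, yy - cy)
    shading = _shading(PHANTOM_SHAPE)

    planes: dict[str, DynamicSeries] = {}
    pd_images: dict[str, np.ndarray] = {}
    t1maps: dict[str, T1Map] = {}
    contours: dict[str, Contours] = {}

    # ------- short-axis myocardial planes ------------------------------
    rv_point = np.array([cx, cy + EPI_RADIUS_MM + 4.0])  # superior
    th0 = np.arctan2(rv_point[1] - cy, rv_point[0] - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    rel = np.mod(theta - th0, 2 * np.pi)

    body = rr <= BODY_RADIUS_MM
    cavity = rr < ENDO_RADIUS_MM
    wall = (rr >= ENDO_RADIUS_MM) & (rr <= EPI_RADIUS_MM)

    t1_sa = np.full(PHANTOM_SHAPE, np.nan)
    t1_sa[body] = T1_BODY
    t1_sa[wall] = T1_MYO
    t1_sa[cavity] = T1_BLOOD
    acq_myo = AcquisitionParams.myo_plane()

    base_aif = patient.base_aif[phase].values
    for level, (seg0, nseg) in _SLICE_SEGMENTS.items():
        conc = np.zeros((len(frames), ny, nx))
        conc[:, cavity] = base_aif[:, None]
        wedge_width = 2 * np.pi / nseg
        tissue_curves = patient.tissue_clean.get(phase) or patient.tissue[phase]
        for s in range(nseg):
            in_seg = wall & (rel >= s * wedge_width) & (rel < (s + 1) * wedge_width)
            conc[:, in_seg] = tissue_curves[seg0 + s].values[:, None]
        sig = concentration_to_signal(conc, np.nan_to_num(t1_sa, nan=T1_BODY), acq_myo,
                                      scale=SIGNAL_SCALE * shading)
        sig[:, ~body] = 0.0
        if signal_noise_sd > 0:
            sig = sig + rng.normal(0.0, signal_noise_sd, size=sig.shape)
        planes[level] = DynamicSeries(
            sig, frames, PIXEL_SPACING_MM, "myocardium", mask=body.copy()
        )
        pd_images[level] = np.stack([SIGNAL_SCALE * shading * body] * 2)
        t1maps[level] = T1Map(t1_sa.copy(), PIXEL_SPACING_MM)
        ang = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        contours[level] = Contours(
            np.column_stack([cx + ENDO_RADIUS_MM * np.cos(ang), cy + ENDO_RADIUS_MM * np.sin(ang)]),
            np.column_stack([cx + EPI_RADIUS_MM * np.cos(ang), cy + EPI_RADIUS_MM * np.sin(ang)]),
            rv_point,
            slice_level=level,
        )

    # ------- low-resolution 3-chamber plane ----------------------------
    acq_aif = AcquisitionParams.aif_plane()
    t1_3ch = np.full(PHANTOM_SHAPE, T1_BODY)
    conc = np.zeros((len(frames), ny, nx))
    rois = {}
    aif_curves = patient.aifs_clean.get(phase) or patient.aifs[phase]
    for loc in AIF_LOCATIONS:
        px, py = _ROI_CENTERS_MM[loc]
        pool = np.hypot(xx - px, yy - py) <= _AIF_POOL_RADIUS_MM
        conc[:, pool] = aif_curves[loc].values[:, None]
        t1_3ch[pool] = T1_BLOOD
        rois[loc] = RoiSpec(loc, (px, py), 10.0)
    sig = concentration_to_signal(conc, t1_3ch, acq_aif, scale=SIGNAL_SCALE * shading)
    if signal_noise_sd > 0:
        sig = sig + rng.normal(0.0, signal_noise_sd, size=sig.shape)
    planes["3ch"] = DynamicSeries(sig, frames, PIXEL_SPACING_MM, "aif")
    pd_images["3ch"] = np.stack([SIGNAL_SCALE * shading] * 2)
    t1maps["3ch"] = T1Map(t1_3ch, PIXEL_SPACING_MM)

    return {
        "planes": planes,
        "pd": pd_images,
        "t1": t1maps,
        "contours": contours,
        "rois": rois,
        "lv_center": (cx, cy),
        "phase": phase,
    }
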