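"""Polar resampling of MBF maps and AHA 16-segment reduction.

Pixel-wise MBF inside the myocardium (between manually drawn
endocardial and epicardial contours) is interpolated onto a polar grid
of 60 angular positions x 10 transmural layers anchored at the superior
RV insertion point, then averaged into the 16 segments of the AHA model
(6 basal, 6 mid, 4 apical). Angular position 0 sits at the RV insertion
and proceeds counterclockwise in the standard short-axis display;
transmural layer 1 is endocardial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from cmrperf.fermi import PixelMap

__all__ = [
    "Contours",
    "PolarMap",
    "to_polar",
    "to_aha_segments",
    "compute_mpr",
    "N_ANGULAR",
    "N_TRANSMURAL",
]

N_ANGULAR = 60
N_TRANSMURAL = 10

#: AHA segment spans as (ring, first angular position, n positions)
_BASAL_SEGMENTS = [(0, i * 10, 10) for i in range(6)]  # segments 1-6
_MID_SEGMENTS = [(1, i * 10, 10) for i in range(6)]  # segments 7-12
_APICAL_SEGMENTS = [(2, i * 15, 15) for i in range(4)]  # segments 13-16


@dataclass
class Contours:
    """Endo/epicardial polygons (mm, (N,2) arrays of x,y) with the
    superior RV insertion point; the wall is assumed star-shaped about
    the endocardial centroid (true for short-axis LV anatomy)."""

    endo: np.ndarray
    epi: np.ndarray
    rv_insertion: np.ndarray
    slice_level: str = "mid"

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        self.rv_insertion = np.asarray(self.rv_insertion, dtype=float)
        if self.endo.ndim != 2 or self.endo.shape[1] != 2 or len(self.endo) < 3:
            raise ValueError("endo must be an (N,2) polygon")
        if self.epi.ndim != 2 or self.epi.shape[1] != 2 or len(self.epi) < 3:
            raise ValueError("epi must be an (N,2) polygon")
        c = self.center
        th = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        re = _radius_at(self.endo, c, th)
        rp = _radius_at(self.epi, c, th)
        if np.any(rp - re <= 0):
            raise ValueError("endocardial contour must lie strictly inside the epicardial one")
        rv_r = float(np.hypot(*(self.rv_insertion - c)))
        th_rv = np.arctan2(self.rv_insertion[1] - c[1], self.rv_insertion[0] - c[0])
        if rv_r < float(_radius_at(self.endo, c, np.array([th_rv]))[0]):
            raise ValueError("RV insertion point lies inside the endocardium")

    @property
    def center(self) -> np.ndarray:
        return self.endo.mean(axis=0)


def _radius_at(poly: np.ndarray, center: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Boundary radius of a star-shaped polygon at the given angles."""
    d = poly - center
    ang = np.arctan2(d[:, 1], d[:, 0]) % (2 * np.pi)
    rad = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(ang)
    return np.interp(theta % (2 * np.pi), ang[order], rad[order], period=2 * np.pi)


@dataclass
class PolarMap:
    """60 x 10 (angular x transmural) mean-MBF grid for one slice."""

    values: np.ndarray
    filled: np.ndarray = field(default=None)  # cells inherited from a neighbor
    slice_level: str = "mid"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_ANGULAR, N_TRANSMURAL):
            raise ValueError(f"polar grid must be {N_ANGULAR}x{N_TRANSMURAL}")
        if self.filled is None:
            self.filled = np.zeros_like(self.values, dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.values.size


def to_polar(pixel_map: PixelMap, contours: Contours) -> PolarMap:
    """Resample a pixel-wise MBF map onto the 60x10 polar grid.

    Each cell is sampled bilinearly at its center: angle
    (i + 0.5) * 6 degrees counterclockwise from the RV insertion, depth
    (k + 0.5)/10 of the local wall thickness from the endocardium.
    Cells landing on invalid pixels inherit the nearest valid cell at
    the same depth along the angular direction and are flagged.
    """
    c = contours.center
    rv = contours.rv_insertion - c
    th0 = np.arctan2(rv[1], rv[0])
    ang = th0 + 2 * np.pi * (np.arange(N_ANGULAR) + 0.5) / N_ANGULAR
    re = _radius_at(contours.endo, c, ang)
    rp = _radius_at(contours.epi, c, ang)
    if np.any(rp - re <= 0):
        raise ValueError("degenerate contours: zero wall thickness")
    depth = (np.arange(N_TRANSMURAL) + 0.5) / N_TRANSMURAL
    r = re[:, None] + depth[None, :] * (rp - re)[:, None]
    x = c[0] + r * np.cos(ang)[:, None]
    y = c[1] + r * np.sin(ang)[:, None]
    sp = pixel_map.pixel_spacing
    # restrict sampling to pixels between the contours: values outside the
    # wall (cavity blood, background) must not bleed into boundary cells
    ny, nx = pixel_map.mbf.shape
    pxx, pyy = np.meshgrid(np.arange(nx) * sp, np.arange(ny) * sp)
    pr = np.hypot(pxx - c[0], pyy - c[1])
    pth = np.arctan2(pyy - c[1], pxx - c[0])
    in_wall = (pr >= _radius_at(contours.endo, c, pth.ravel()).reshape(pr.shape)) & (
        pr <= _radius_at(contours.epi, c, pth.ravel()).reshape(pr.shape)
    )
    valid = pixel_map.valid & in_wall
    # map_coordinates indexes (row, col) = (y, x) in pixel units
    coords = np.vstack([(y / sp).ravel(), (x / sp).ravel()])
    filled_map = np.where(valid, pixel_map.mbf, 0.0)
    vals = map_coordinates(filled_map, coords, order=1, mode="nearest")
    wts = map_coordinates(valid.astype(float), coords, order=1, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        cell = np.where(wts > 0.05, vals / np.maximum(wts, 1e-12), np.nan)
    cell = cell.reshape(N_ANGULAR, N_TRANSMURAL)

    filled = np.zeros_like(cell, dtype=bool)
    for k in range(N_TRANSMURAL):
        col = cell[:, k]
        bad = ~np.isfinite(col)
        if bad.all():
            raise ValueError(f"no valid pixels anywhere at transmural layer {k + 1}")
        if bad.any():
            idx = np.arange(N_ANGULAR)
            good = idx[~bad]
            for i in idx[bad]:
                # nearest valid angular neighbor on the ring
                d = np.minimum((good - i) % N_ANGULAR, (i - good) % N_ANGULAR)
                col[i] = col[good[np.argmin(d)]]
                filled[i, k] = True
        cell[:, k] = col
    return PolarMap(cell, filled, contours.slice_level)


def to_aha_segments(
    polar_basal: PolarMap, polar_mid: PolarMap, polar_apical: PolarMap
) -> np.ndarray:
    """Collapse three polar maps into the 16 AHA segment means.

    Segments 1-6 are basal (10 angular positions each), 7-12 mid, and
    13-16 apical (15 positions each); each mean pools all 10 transmural
    layers. Numbering starts at the RV insertion (anterior wall) and
    proceeds counterclockwise, following the standard display.
    """
    rings = (polar_basal, polar_mid, polar_apical)
    for ring in rings:
        if ring.values.shape != (N_ANGULAR, N_TRANSMURAL):
            raise ValueError("polar maps must be 60x10")
    out = np.empty(16)
    for seg, (ring_idx, a0, na) in enumerate(_BASAL_SEGMENTS + _MID_SEGMENTS + _APICAL_SEGMENTS):
        out[seg] = rings[ring_idx].values[a0 : a0 + na, :].mean()
    return out


#: columns of the tidy segment table used across the package
SEGMENT_TABLE_COLUMNS = [
    "patient",
    "segment",
    "location",
    "stress_mbf",
    "rest_mbf",
    "mpr",
    "label",
]


def compute_mpr(
    stress: pd.DataFrame, rest: pd.DataFrame, rest_floor: float = 0.05
) -> pd.DataFrame:
    """Merge stress and rest segment tables and add MPR = stress/rest.

    Both tables need columns (patient, segment, location, mbf). Rows
    whose rest MBF is at or below ``rest_floor`` (mL/g/min) get an
    undefined (NaN) MPR and ``mpr_undefined = True`` — never infinity.
    """
    keys = ["patient", "segment", "location"]
    for name, df in (("stress", stress), ("rest", rest)):
        if not set(keys + ["mbf"]).issubset(df.columns):
            raise ValueError(f"{name} table lacks required columns")
    merged = stress.rename(columns={"mbf": "stress_mbf"}).merge(
        rest.rename(columns={"mbf": "rest_mbf"})[keys + ["rest_mbf"]],
        on=keys,
        how="inner",
        validate="one_to_one",
    )
    if len(merged) != len(stress) or len(merged) != len(rest):
        raise ValueError("stress and rest tables do not describe the same segments")
    ok = merged["rest_mbf"] > rest_floor
    merged["mpr"] = np.where(ok, merged["stress_mbf"] / merged["rest_mbf"], np.nan)
    merged["mpr_undefined"] = ~ok
    return merged
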