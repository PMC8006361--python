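"""In-memory containers for dynamic perfusion image data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AIF_LOCATIONS = ("LA", "bLV", "mLV", "aLV", "AoR")
"""AIF sampling locations on the low-resolution 3-chamber plane:
left atrium, basal/mid/apical left-ventricular cavity, aortic root."""

MYO_SLICES = ("basal", "mid", "apical")


@dataclass
class DynamicSeries:
    """A time-resolved image stack for one imaging plane.

    Parameters
    ----------
    data : ndarray, shape (n_frames, ny, nx)
        Pixel values (signal intensity or gadolinium concentration, mM).
    frame_times : ndarray, shape (n_frames,)
        Acquisition time of each frame in seconds, strictly increasing.
    pixel_spacing : float
        In-plane pixel size in mm (isotropic).
    plane_role : str
        ``"aif"`` for the low-resolution 3-chamber plane, ``"myocardium"``
        for the short-axis planes.
    mask : ndarray of bool, shape (ny, nx), optional
        True where pixels are valid. Defaults to all-valid.
    """

    data: np.ndarray
    frame_times: np.ndarray
    pixel_spacing: float
    plane_role: str = "myocardium"
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_frames, ny, nx)")
        if len(self.frame_times) != self.data.shape[0]:
            raise ValueError("frame_times length must match n_frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class T1Map:
    """Per-pixel native (pre-contrast) T1 in seconds.

    Invalid pixels (outside the body, failed fits) are NaN; ``valid``
    exposes the usable mask.
    """

    t1: np.ndarray
    pixel_spacing: float = 1.3

    def __post_init__(self) -> None:
        self.t1 = np.asarray(self.t1, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(self.t1[np.isfinite(self.t1)] <= 0):
                raise ValueError("T1 must be positive where defined")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.t1) & (self.t1 > 0)
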