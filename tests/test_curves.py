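"""Curve conditioning: ROI extraction, shape-preserving interpolation,
triangle-method onset, first/second-pass split and the 20-s window rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmrperf.curves import (
    ConcentrationCurve,
    RoiSpec,
    condition_aif,
    crop_window,
    detect_upslope_start,
    extract_roi_curve,
    interpolate_uniform,
    split_passes,
    subtract_baseline,
)
from cmrperf.imagedata import DynamicSeries
from cmrperf.synthetic import BolusParams, gamma_variate_aif


def _curve(times, values):
    return ConcentrationCurve(np.asarray(times, float), np.asarray(values, float))


class TestRoiExtraction:
    def _series(self, nframes=4, n=64, spacing=1.3, value=None):
        data = np.ones((nframes, n, n)) if value is None else value
        return DynamicSeries(data, np.arange(nframes, dtype=float), spacing)

    def test_constant_frame_value(self):
        series = self._series(value=3.7 * np.ones((4, 64, 64)))
        c = extract_roi_curve(series, RoiSpec("AoR", (40.0, 40.0)))
        np.testing.assert_allclose(c.values, 3.7)

    def test_pixel_count_center_in_circle(self):
        """A 10-mm ROI on a 1.3-mm grid includes 45-49 pixel centers."""
        series = self._series()
        marker = np.zeros((64, 64))
        s2 = DynamicSeries(marker[None], np.array([0.0]), 1.3)
        # count via an indicator ROI: place ROI on a pixel center
        center = (32 * 1.3, 32 * 1.3)
        ys, xs = np.meshgrid(np.arange(64) * 1.3, np.arange(64) * 1.3, indexing="ij")
        n_inside = int(np.sum((xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= 25.0))
        assert 45 <= n_inside <= 49
        c = extract_roi_curve(series, RoiSpec("bLV", center))
        assert len(c) == 4

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValueError):
            extract_roi_curve(self._series(), RoiSpec("LA", (2.0, 2.0)))

    def test_fully_masked_roi_rejected(self):
        series = self._series()
        series.mask[:, :] = False
        with pytest.raises(ValueError, match="no valid pixels"):
            extract_roi_curve(series, RoiSpec("LA", (40.0, 40.0)))


class TestInterpolation:
    def test_knots_preserved_when_already_uniform(self):
        t = np.arange(0, 10, 0.5)
        v = np.sin(t)
        out = interpolate_uniform(_curve(t, v), 0.5)
        np.testing.assert_allclose(out.values, v, atol=1e-12)

    def test_monotone_segments_stay_monotone(self):
        t = np.array([0, 1, 2, 3, 4, 5, 6.0])
        v = np.array([0, 0, 1, 3, 3.5, 3.6, 3.65])
        out = interpolate_uniform(_curve(t, v), 0.1)
        assert np.all(np.diff(out.values) >= -1e-12)

    def test_jittered_grid_error_below_1pct_of_peak(self, rng):
        """Resampling a smooth bolus from a jittered RR grid stays
        within 1% of the closed form."""
        rr = 0.9 * (1 + 0.05 * rng.uniform(-1, 1, size=70))
        t = np.concatenate([[0.0], np.cumsum(rr)])
        params = BolusParams()
        sampled = gamma_variate_aif(params, t)
        out = interpolate_uniform(sampled, 0.5)
        truth = gamma_variate_aif(params, out.times)
        assert np.max(np.abs(out.values - truth.values)) < 0.01 * truth.values.max()

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            interpolate_uniform(_curve([0, 1, 2, 3], [0, 1, 2, 3]), 0.0)


class TestOnsetDetection:
    def test_piecewise_linear_breakpoint(self):
        """Flat baseline then linear rise: onset at the breakpoint,
        verified against a brute-force distance maximization."""
        t = np.arange(0, 30, 0.5)
        v = np.where(t < 10, 0.0, (t - 10) * 0.4)
        onset = detect_upslope_start(_curve(t, v))
        assert abs(onset - 10.0) <= 0.5

        # brute-force chord-distance oracle on the normalized segment:
        # the refined onset stays within one sample of the triangle point
        p = int(np.argmax(v))
        ts = (t[: p + 1] - t[0]) / (t[p] - t[0])
        vs = (v[: p + 1] - v[0]) / (v[p] - v[0])
        k = int(np.argmax(ts - vs))
        assert abs(onset - t[k]) <= 0.5

    @pytest.mark.parametrize("onset_true", [3.0, 7.0, 12.0, 20.0])
    def test_gamma_variate_onset_within_one_sample(self, onset_true):
        t = np.arange(0.0, 45.0, 0.5)
        c = gamma_variate_aif(BolusParams(onset_time=onset_true, recirc_fraction=0.0), t)
        assert abs(detect_upslope_start(c) - onset_true) <= 0.5

    def test_pure_ramp_flagged_degenerate(self):
        t = np.arange(0, 10, 0.5)
        c = _curve(t, t * 1.0)
        detect_upslope_start(c)
        assert "degenerate_onset" in c.flags

    def test_constant_curve_rejected(self):
        with pytest.raises(ValueError):
            detect_upslope_start(_curve(np.arange(10.0), np.ones(10)))

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_amplitude_scale_invariance(self, scale):
        t = np.arange(0.0, 45.0, 0.5)
        c = gamma_variate_aif(BolusParams(onset_time=9.0), t)
        scaled = _curve(t, c.values * scale)
        assert detect_upslope_start(scaled) == pytest.approx(
            detect_upslope_start(c), abs=1e-9
        )


class TestPassSplit:
    def _with_onset(self, t, v):
        c = _curve(t, v)
        detect_upslope_start(c)
        return c

    def test_two_gamma_variates_trough(self):
        """Sum of bumps peaking at 12 and 30 s: split at the trough,
        located by brute force between the analytic peaks."""
        t = np.arange(0.0, 50.0, 0.5)
        a = gamma_variate_aif(BolusParams(6.0, 8.0, 3.0, 4 / 3, recirc_fraction=0.0), t).values
        b = gamma_variate_aif(BolusParams(2.5, 26.0, 3.0, 4 / 3, recirc_fraction=0.0), t).values
        c = self._with_onset(t, a + b)
        split = split_passes(c)
        between = (t > 12) & (t < 30)
        t_trough = t[between][np.argmin((a + b)[between])]
        assert split == pytest.approx(t_trough, abs=0.5)

    def test_single_pass_no_split(self):
        t = np.arange(0.0, 40.0, 0.5)
        c = gamma_variate_aif(BolusParams(recirc_fraction=0.0), t)
        detect_upslope_start(c)
        assert split_passes(c) is None
        assert "no_second_pass" in c.flags

    def test_monotone_rise_degenerate(self):
        t = np.arange(0.0, 20.0, 0.5)
        c = self._with_onset(t, np.concatenate([np.zeros(10), np.linspace(0, 5, 30)]))
        assert split_passes(c) is None
        assert "degenerate_peaks" in c.flags or "no_second_pass" in c.flags

    def test_landmark_ordering_on_realistic_aif(self):
        t = np.arange(0.0, 60.0, 0.5)
        c = gamma_variate_aif(BolusParams(), t)
        cc = condition_aif(ConcentrationCurve(t, c.values))
        lm = cc.landmarks
        assert lm["upslope_start"] < lm["first_pass_peak"] < lm["pass_split"]


class TestCropWindow:
    def _aif(self, onset, split, end=60.0):
        t = np.arange(0.0, end + 1e-9, 0.5)
        c = _curve(t, np.zeros_like(t))
        c.landmarks["upslope_start"] = onset
        if split is not None:
            c.landmarks["pass_split"] = split
        return c

    def test_short_window_extended_to_exactly_20s(self):
        aif, _ = crop_window(self._aif(10.0, 22.0))
        assert aif.landmarks["crop"] == [10.0, 30.0]
        assert aif.times[-1] - aif.times[0] == pytest.approx(20.0)

    def test_long_window_untouched(self):
        aif, _ = crop_window(self._aif(10.0, 38.0))
        assert aif.landmarks["crop"] == [10.0, 38.0]

    def test_acquisition_too_short_warns(self):
        with pytest.warns(UserWarning, match="shorter"):
            aif, _ = crop_window(self._aif(10.0, None, end=24.0))
        assert aif.landmarks["crop"] == [10.0, 24.0]
        assert "short_window" in aif.flags

    def test_tissues_cropped_to_same_window(self):
        t = np.arange(0.0, 60.0 + 1e-9, 0.5)
        tissue = _curve(t, np.random.default_rng(1).normal(size=t.size))
        aif, tissues = crop_window(self._aif(10.0, 22.0), [tissue])
        assert len(tissues[0]) == len(aif)
        np.testing.assert_array_equal(tissues[0].times, aif.times)

    def test_inverted_landmarks_rejected(self):
        bad = self._aif(25.0, 20.0)
        with pytest.raises(ValueError):
            crop_window(bad)


class TestBaseline:
    def test_pre_onset_mean_removed(self):
        t = np.arange(0.0, 30.0, 0.5)
        v = np.where(t < 10, 2.0, 7.0)
        out = subtract_baseline(_curve(t, v), onset=10.0)
        assert out.values[0] == pytest.approx(0.0)
        assert out.values[-1] == pytest.approx(5.0)
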