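"""Stimulated-ROI partition, pulse matching, calibration, power response."""

import numpy as np
import pytest

from calimetry.errors import FitError, FormatError
from calimetry.events import RoiEvents
from calimetry.evoked import (
    StimProtocol,
    classify_rois,
    fit_led_calibration,
    match_peaks_to_pulses,
    power_response,
    stim_field_area,
)

from _oracles import evoked_match_oracle


def _mask_with_roi(n_px_total, n_px_inside):
    """One 100x1-style ROI with a stim mask covering its first pixels."""
    label = np.zeros((n_px_total, 2), dtype=np.int32)
    label[:, 0] = 1
    stim = np.zeros_like(label, dtype=bool)
    stim[:n_px_inside, 0] = True
    return label, stim


class TestClassifyRois:
    def test_full_overlap_is_stimulated(self):
        label, stim = _mask_with_roi(20, 20)
        out = classify_rois(label, stim)
        assert list(out["stimulated"]) == [1]

    def test_exactly_ten_percent_is_not_stimulated(self):
        label, stim = _mask_with_roi(100, 10)  # overlap exactly 0.10
        out = classify_rois(label, stim)
        assert list(out["non_stimulated"]) == [1]
        assert len(out["stimulated"]) == 0

    def test_eleven_percent_is_stimulated(self):
        label, stim = _mask_with_roi(100, 11)
        out = classify_rois(label, stim)
        assert list(out["stimulated"]) == [1]

    def test_partition_covers_all_rois(self, rng):
        label = rng.integers(0, 6, (40, 40)).astype(np.int32)
        stim = rng.random((40, 40)) < 0.3
        out = classify_rois(label, stim)
        all_ids = sorted(
            list(out["stimulated"]) + list(out["non_stimulated"])
        )
        assert all_ids == sorted(np.unique(label[label > 0]).tolist())

    def test_shape_mismatch(self):
        with pytest.raises(FormatError):
            classify_rois(np.zeros((4, 4), dtype=int), np.zeros((8, 8), dtype=bool))


class TestMatchPeaks:
    def _events(self, frames):
        frames = np.asarray(frames, dtype=np.int64)
        return RoiEvents(frames, np.ones(len(frames)))

    def test_window_boundaries(self):
        ev = match_peaks_to_pulses(self._events([54, 55]), np.array([50]), 5)
        assert list(ev.evoked) == [True, False]

    def test_peak_before_first_pulse(self):
        ev = match_peaks_to_pulses(self._events([49]), np.array([50]), 5)
        assert list(ev.evoked) == [False]
        assert list(ev.pulse_index) == [-1]

    def test_overlapping_windows_attribute_later_pulse(self):
        ev = match_peaks_to_pulses(self._events([13]), np.array([10, 12]), 5)
        assert list(ev.evoked) == [True]
        assert list(ev.pulse_index) == [1]

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(200):
            n_pulses = int(rng.integers(0, 15))
            onsets = np.sort(
                rng.choice(500, size=n_pulses, replace=False)
            ).astype(np.int64)
            frames = np.sort(
                rng.choice(500, size=int(rng.integers(0, 25)), replace=False)
            ).astype(np.int64)
            w = int(rng.integers(1, 9))
            got = match_peaks_to_pulses(self._events(frames), onsets, w)
            want_ev, want_idx = evoked_match_oracle(frames, onsets, w)
            np.testing.assert_array_equal(got.evoked, want_ev)
            np.testing.assert_array_equal(got.pulse_index, want_idx)


class TestCalibration:
    def test_linear_exact(self):
        x = np.array([1.0, 2, 5, 10])
        cal = fit_led_calibration(x, 10.0 * x, "linear")
        np.testing.assert_allclose(cal.coefficients, [10.0, 0.0], atol=1e-9)
        assert cal.fit_residual < 1e-9

    def test_power_law_log_log_recovery(self):
        x = np.array([1.0, 2, 4, 8])
        y = 2.0 * x**1.5
        cal = fit_led_calibration(x, y, "power_law")
        np.testing.assert_allclose(cal.coefficients, [2.0, 1.5], atol=1e-6)

    @pytest.mark.parametrize(
        "form,coef,fn",
        [
            ("linear", [3.0, -1.0], lambda x: 3.0 * x - 1.0),
            ("quadratic", [0.5, 2.0, 1.0], lambda x: 0.5 * x**2 + 2 * x + 1),
            ("exponential", [2.0, 0.3, 1.0], lambda x: 2 * np.exp(0.3 * x) + 1),
            ("power_law", [2.0, 1.5], lambda x: 2.0 * x**1.5),
            ("logarithmic", [4.0, 0.5], lambda x: 4.0 * np.log(x) + 0.5),
        ],
    )
    def test_all_forms_round_trip(self, form, coef, fn):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0, 10.0])
        cal = fit_led_calibration(x, fn(x), form)
        np.testing.assert_allclose(cal.coefficients, coef, atol=1e-6)
        assert cal.fit_residual < 1e-8
        np.testing.assert_allclose(cal.predict(x), fn(x), atol=1e-6)

    def test_underdetermined_raises(self):
        with pytest.raises(FitError):
            fit_led_calibration(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                                "quadratic")

    def test_nonpositive_power_domain_error(self):
        with pytest.raises(FitError):
            fit_led_calibration(np.array([0.0, 1.0, 2.0]),
                                np.array([1.0, 2.0, 3.0]), "logarithmic")


class TestPowerResponse:
    def test_mean_and_sem(self):
        protocol = StimProtocol(
            pulse_onset_frames=np.array([10, 50, 90]),
            pulse_duration_ms=100.0,
            led_power_pct=np.array([5.0, 5.0, 5.0]),
            irradiance_mw_cm2=np.array([48.0, 48.0, 48.0]),
        )
        ev = RoiEvents(
            np.array([11, 51, 91]), np.array([1.0, 2.0, 3.0]),
            evoked=np.array([True, True, True]),
            pulse_index=np.array([0, 1, 2]),
        )
        out = power_response({1: ev}, {"stimulated": np.array([1]),
                                       "non_stimulated": np.array([])}, protocol)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(0.5773502691896258)
        assert row["n"] == 3

    def test_empty_groups_omitted(self):
        protocol = StimProtocol(
            pulse_onset_frames=np.array([10]),
            pulse_duration_ms=100.0,
            led_power_pct=np.array([5.0]),
        )
        ev = RoiEvents(np.array([200]), np.array([1.0]),
                       evoked=np.array([False]), pulse_index=np.array([-1]))
        out = power_response({1: ev}, {"stimulated": np.array([1]),
                                       "non_stimulated": np.array([])}, protocol)
        assert len(out) == 0


class TestStimFieldArea:
    def test_80um_field(self):
        assert stim_field_area(80.0) == pytest.approx(5026.548, abs=1e-3)

    def test_unit_radius(self):
        assert stim_field_area(2.0) == pytest.approx(np.pi)

    def test_zero_diameter_raises(self):
        with pytest.raises(ValueError):
            stim_field_area(0.0)
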