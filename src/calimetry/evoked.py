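"""All-optical evoked-activity analysis.

ROIs are partitioned into stimulated / non-stimulated by their overlap with
a binary stimulation mask: a cell counts as stimulated when strictly more
than 10% of its pixels fall inside the mask.  Detected peaks are labelled
evoked when they fall inside a short window following a stimulation pulse
(default five frames including the onset frame, i.e. frames ``p .. p+4``);
the preceding pulse is found by binary search over the sorted onsets and a
peak inside two overlapping windows is attributed to the later pulse.

LED power (% of driver range) maps to irradiance at the sample through one
of five calibration families — linear, quadratic, exponential, power-law,
logarithmic — fitted by least squares.  Evoked peak amplitudes grouped by
the irradiance of their attributed pulse give the irradiance-response
table (mean +/- SEM per ROI class and level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar

from .errors import FitError, FormatError
from .events import RoiEvents

__all__ = [
    "StimProtocol",
    "LedCalibration",
    "classify_rois",
    "match_peaks_to_pulses",
    "fit_led_calibration",
    "power_response",
    "stim_field_area",
    "OVERLAP_THRESHOLD",
    "DEFAULT_EVOKED_WINDOW_FRAMES",
]

OVERLAP_THRESHOLD = 0.10
DEFAULT_EVOKED_WINDOW_FRAMES = 5


@dataclass
class StimProtocol:
    """Optogenetic stimulation log for one field of view."""

    pulse_onset_frames: np.ndarray        # sorted, strictly increasing
    pulse_duration_ms: float
    led_power_pct: np.ndarray             # one per pulse
    irradiance_mw_cm2: np.ndarray | None = None  # one per pulse
    stim_mask: np.ndarray | None = None   # binary Y x X image

    def __post_init__(self) -> None:
        self.pulse_onset_frames = np.asarray(self.pulse_onset_frames, dtype=np.int64)
        self.led_power_pct = np.asarray(self.led_power_pct, dtype=np.float64)
        if np.any(np.diff(self.pulse_onset_frames) <= 0):
            raise ValueError("pulse onsets must be strictly increasing")
        if len(self.led_power_pct) != len(self.pulse_onset_frames):
            raise ValueError("one LED power per pulse required")
        if self.irradiance_mw_cm2 is not None:
            self.irradiance_mw_cm2 = np.asarray(self.irradiance_mw_cm2, dtype=np.float64)
            if np.any(self.irradiance_mw_cm2 < 0):
                raise ValueError("irradiance must be >= 0")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_onset_frames)


def classify_rois(
    label_mask: np.ndarray,
    stim_mask: np.ndarray,
    threshold: float = OVERLAP_THRESHOLD,
) -> dict[str, np.ndarray]:
    """Partition ROI ids by stimulation-mask overlap (strict > threshold)."""
    label_mask = np.asarray(label_mask)
    stim = np.asarray(stim_mask).astype(bool)
    if label_mask.shape != stim.shape:
        raise FormatError(
            f"stim mask shape {stim.shape} does not match label mask "
            f"shape {label_mask.shape}"
        )
    ids = np.unique(label_mask)
    ids = ids[ids > 0]
    total = np.bincount(label_mask.ravel(), minlength=int(ids.max()) + 1 if ids.size else 1)
    inside = np.bincount(
        label_mask.ravel(), weights=stim.ravel(), minlength=len(total)
    )
    frac = np.zeros(len(total))
    nz = total > 0
    frac[nz] = inside[nz] / total[nz]
    stimulated = ids[frac[ids] > threshold]
    non_stimulated = ids[frac[ids] <= threshold]
    return {
        "stimulated": stimulated.astype(np.int64),
        "non_stimulated": non_stimulated.astype(np.int64),
    }


def match_peaks_to_pulses(
    events: RoiEvents,
    pulse_onset_frames: np.ndarray,
    window_frames: int = DEFAULT_EVOKED_WINDOW_FRAMES,
) -> RoiEvents:
    """Label each peak evoked iff a pulse onset p satisfies p <= f <= p+w-1.

    The latest qualifying pulse is attributed (binary search via
    ``np.searchsorted``); peaks before the first pulse are spontaneous.
    Returns a new RoiEvents with ``evoked`` and ``pulse_index`` filled.
    """
    onsets = np.asarray(pulse_onset_frames, dtype=np.int64)
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    frames = events.peak_frames
    if onsets.size == 0:
        evoked = np.zeros(len(frames), dtype=bool)
        idx = np.full(len(frames), -1, dtype=np.int64)
    else:
        # index of the latest onset <= peak frame
        idx = np.searchsorted(onsets, frames, side="right") - 1
        has_prev = idx >= 0
        dist = np.where(has_prev, frames - onsets[np.clip(idx, 0, None)], window_frames)
        evoked = has_prev & (dist <= window_frames - 1)
        idx = np.where(evoked, idx, -1)
    return RoiEvents(
        peak_frames=frames.copy(),
        peak_amplitudes=events.peak_amplitudes.copy(),
        evoked=evoked,
        pulse_index=idx,
    )


@dataclass
class LedCalibration:
    """Fitted power (%) -> irradiance (mW/cm^2) mapping."""

    form: str
    coefficients: np.ndarray
    fit_residual: float   # sqrt of mean squared residual

    _FORMS = ("linear", "quadratic", "exponential", "power_law", "logarithmic")

    def predict(self, power_pct: np.ndarray) -> np.ndarray:
        x = np.asarray(power_pct, dtype=np.float64)
        c = self.coefficients
        if self.form == "linear":
            return c[0] * x + c[1]
        if self.form == "quadratic":
            return c[0] * x**2 + c[1] * x + c[2]
        if self.form == "exponential":
            return c[0] * np.exp(c[1] * x) + c[2]
        if self.form == "power_law":
            return c[0] * np.power(x, c[1])
        if self.form == "logarithmic":
            return c[0] * np.log(x) + c[1]
        raise ValueError(f"unknown form {self.form!r}")


def _fit_exponential(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """a*exp(b*x)+c by profiling: for fixed b, (a, c) solve linearly."""

    def profiled_rss(b: float) -> tuple[float, np.ndarray]:
        design = np.column_stack([np.exp(np.clip(b * x, -500, 500)), np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = design @ coef - y
        return float(resid @ resid), coef

    span = np.ptp(x) if np.ptp(x) > 0 else 1.0
    grid = np.linspace(-10.0 / span, 10.0 / span, 201)
    grid = grid[grid != 0.0]
    rss_grid = [profiled_rss(b)[0] for b in grid]
    b0 = grid[int(np.argmin(rss_grid))]
    res = minimize_scalar(
        lambda b: profiled_rss(b)[0],
        bounds=(b0 - 0.2 / span, b0 + 0.2 / span),
        method="bounded",
        options={"xatol": 1e-13},
    )
    b_best = float(res.x)
    rss, coef = profiled_rss(b_best)
    # polish with full nonlinear least squares
    try:
        popt, _ = curve_fit(
            lambda t, a, b, c: a * np.exp(b * t) + c,
            x, y, p0=[coef[0], b_best, coef[1]], maxfev=20000,
        )
        if np.all(np.isfinite(popt)):
            pred = popt[0] * np.exp(popt[1] * x) + popt[2]
            if float(np.sum((pred - y) ** 2)) <= rss + 1e-30:
                return popt
    except RuntimeError:
        pass
    return np.array([coef[0], b_best, coef[1]])


def fit_led_calibration(
    power_pct: np.ndarray,
    irradiance: np.ndarray,
    form: str,
) -> LedCalibration:
    """Least-squares fit of the chosen calibration family.

    Linear/quadratic/logarithmic are linear least squares; power-law is a
    closed-form log-log regression (requires positive powers and
    irradiances); exponential profiles the rate with linear amplitude and
    offset, polished by nonlinear least squares.
    """
    x = np.asarray(power_pct, dtype=np.float64)
    y = np.asarray(irradiance, dtype=np.float64)
    if form not in LedCalibration._FORMS:
        raise ValueError(f"unknown calibration form {form!r}")
    n_coef = {"linear": 2, "quadratic": 3, "exponential": 3,
              "power_law": 2, "logarithmic": 2}[form]
    if len(np.unique(x)) < n_coef:
        raise FitError(
            f"{form} calibration needs >= {n_coef} distinct power points"
        )
    if form in ("power_law", "logarithmic") and np.any(x <= 0):
        raise FitError(f"{form} calibration requires power > 0")

    if form == "linear":
        coef = np.polyfit(x, y, 1)
    elif form == "quadratic":
        coef = np.polyfit(x, y, 2)
    elif form == "logarithmic":
        coef = np.polyfit(np.log(x), y, 1)
    elif form == "power_law":
        if np.any(y <= 0):
            raise FitError("power_law calibration requires irradiance > 0")
        b, loga = np.polyfit(np.log(x), np.log(y), 1)
        coef = np.array([np.exp(loga), b])
    else:  # exponential
        coef = _fit_exponential(x, y)

    cal = LedCalibration(form=form, coefficients=np.asarray(coef, dtype=np.float64),
                         fit_residual=0.0)
    resid = cal.predict(x) - y
    cal.fit_residual = float(np.sqrt(np.mean(resid**2)))
    return cal


def power_response(
    events_by_roi: dict[int, RoiEvents],
    roi_classes: dict[str, np.ndarray],
    protocol: StimProtocol,
) -> pd.DataFrame:
    """Mean +/- SEM evoked amplitude per (ROI class, irradiance level).

    Each evoked peak contributes the denoised amplitude at its peak frame,
    grouped by the irradiance (or, if no calibration is attached, the LED
    power) of the pulse it was attributed to.  Groups with no evoked peaks
    are omitted.  SEM uses the sample standard deviation (ddof=1); a
    single-observation group reports SEM = nan.
    """
    levels = (
        protocol.irradiance_mw_cm2
        if protocol.irradiance_mw_cm2 is not None
        else protocol.led_power_pct
    )
    class_of = {}
    for cls, ids in roi_classes.items():
        for rid in ids:
            class_of[int(rid)] = cls
    rows = []
    for rid, ev in events_by_roi.items():
        if ev.evoked is None:
            raise ValueError("events must be labelled by match_peaks_to_pulses first")
        cls = class_of.get(int(rid))
        if cls is None:
            continue
        for amp, is_ev, pidx in zip(ev.peak_amplitudes, ev.evoked, ev.pulse_index):
            if is_ev:
                rows.append({"roi_class": cls, "level": float(levels[pidx]),
                             "amplitude": float(amp)})
    if not rows:
        return pd.DataFrame(columns=["roi_class", "level", "n", "mean", "sem"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["roi_class", "level"])["amplitude"]
        .agg(n="count", mean="mean", sem=lambda a: a.std(ddof=1) / np.sqrt(len(a)))
        .reset_index()
    )
    return out


def stim_field_area(diameter_um: float) -> float:
    """Area (um^2) of a circular stimulation field of the given diameter."""
    if diameter_um <= 0:
        raise ValueError("diameter must be > 0")
    return float(np.pi * (diameter_um / 2.0) ** 2)
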