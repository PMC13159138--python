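"""Calcium-transient detection and single-cell features.

Peaks are detected on the *denoised* dF/F0 trace.  A candidate peak is a
strict local maximum (a plateau of equal values flanked by strictly smaller
values counts once, placed at its first frame); candidates must exceed the
effective height — either a per-ROI multiple of the estimated noise sigma or
a fixed global value — and have topographic prominence of at least
``prominence_multiplier * sigma``.  A minimum inter-peak distance is then
enforced greedily: peaks are visited in order of descending amplitude
(earlier frame wins ties) and any peak within ``min_distance_frames - 1``
frames of an already-kept peak is discarded.

From the retained events the standard per-ROI features follow: event
frequency (count over recording duration), inter-event intervals, amplitude
statistics (peak values read directly off the denoised trace), cell size
from the mask area, and an active flag (at least one event).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_prominences

__all__ = [
    "PeakParams",
    "RoiEvents",
    "RoiFeatures",
    "detect_peaks",
    "compute_features",
    "percent_active",
]


@dataclass
class PeakParams:
    """Detection thresholds.

    height_mode ``"noise_multiplier"`` makes the minimum peak height
    ``height_value * sigma`` per ROI; ``"global"`` applies ``height_value``
    as an absolute dF/F threshold to every ROI.  The prominence threshold is
    always adaptive: ``prominence_multiplier * sigma``.
    """

    height_mode: str = "noise_multiplier"
    height_value: float = 3.0
    prominence_multiplier: float = 2.0
    min_distance_frames: int = 1

    def __post_init__(self) -> None:
        if self.height_mode not in ("noise_multiplier", "global"):
            raise ValueError("height_mode must be 'noise_multiplier' or 'global'")
        if self.height_value <= 0:
            raise ValueError("height_value must be > 0")
        if self.prominence_multiplier < 0:
            raise ValueError("prominence_multiplier must be >= 0")
        if self.min_distance_frames < 1:
            raise ValueError("min_distance_frames must be >= 1")

    def effective_height(self, sigma: float) -> float:
        if self.height_mode == "noise_multiplier":
            return self.height_value * sigma
        return self.height_value


@dataclass
class RoiEvents:
    """Detected peaks for one ROI; ``evoked`` stays None until the evoked
    analysis labels them."""

    peak_frames: np.ndarray       # sorted ints
    peak_amplitudes: np.ndarray   # denoised dF/F at the peak frames
    evoked: np.ndarray | None = None       # bool per peak
    pulse_index: np.ndarray | None = None  # attributed pulse, -1 if none

    @property
    def n_peaks(self) -> int:
        return len(self.peak_frames)


@dataclass
class RoiFeatures:
    """Scalar features for one ROI."""

    n_events: int
    event_frequency_hz: float
    iei_list_s: np.ndarray
    mean_iei_s: float            # nan when < 2 events
    amplitude_mean: float        # nan when no events
    amplitude_median: float
    cell_size_px: int
    cell_size_um2: float         # nan when pixel size unknown
    active: bool
    extra: dict = field(default_factory=dict)


def _candidate_peaks(x: np.ndarray) -> np.ndarray:
    """Strict local maxima; plateaus collapse to their first frame."""
    peaks, props = find_peaks(x, plateau_size=(1, None))
    return props["left_edges"].astype(np.int64)


def detect_peaks(
    denoised: np.ndarray,
    sigma: float,
    params: PeakParams,
) -> RoiEvents:
    """Detect transients on a denoised trace; an empty result is valid."""
    x = np.asarray(denoised, dtype=np.float64)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    cand = _candidate_peaks(x)
    if cand.size:
        height = params.effective_height(sigma)
        cand = cand[x[cand] >= height]
    if cand.size and params.prominence_multiplier > 0 and sigma > 0:
        prom = peak_prominences(x, cand)[0]
        cand = cand[prom >= params.prominence_multiplier * sigma]
    if cand.size and params.min_distance_frames > 1:
        cand = _enforce_distance(x, cand, params.min_distance_frames)
    cand = np.sort(cand)
    return RoiEvents(peak_frames=cand, peak_amplitudes=x[cand])


def _enforce_distance(x: np.ndarray, cand: np.ndarray, d: int) -> np.ndarray:
    # highest amplitude first; ties resolved in favour of the earlier frame
    order = sorted(range(len(cand)), key=lambda i: (-x[cand[i]], cand[i]))
    kept: list[int] = []
    for i in order:
        f = cand[i]
        if all(abs(f - k) >= d for k in kept):
            kept.append(int(f))
    return np.array(sorted(kept), dtype=np.int64)


def compute_features(
    events: RoiEvents,
    roi_area_px: int,
    pixel_size_um: float | None,
    n_frames: int,
    frame_rate_hz: float,
) -> RoiFeatures:
    """Frequency, IEIs, amplitude statistics and cell size for one ROI."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    n = events.n_peaks
    duration_s = n_frames / frame_rate_hz
    ieis = np.diff(events.peak_frames) / frame_rate_hz if n >= 2 else np.array([])
    amps = events.peak_amplitudes
    return RoiFeatures(
        n_events=n,
        event_frequency_hz=n / duration_s,
        iei_list_s=ieis,
        mean_iei_s=float(np.mean(ieis)) if ieis.size else float("nan"),
        amplitude_mean=float(np.mean(amps)) if n else float("nan"),
        amplitude_median=float(np.median(amps)) if n else float("nan"),
        cell_size_px=int(roi_area_px),
        cell_size_um2=(
            float(roi_area_px) * pixel_size_um**2
            if pixel_size_um is not None
            else float("nan")
        ),
        active=n >= 1,
    )


def percent_active(features: list[RoiFeatures]) -> float:
    """Percentage of ROIs with at least one detected event.

    Returns nan for an empty collection (undefined, reported as missing).
    """
    if not features:
        return float("nan")
    return 100.0 * sum(f.active for f in features) / len(features)
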