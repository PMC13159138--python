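"""End-to-end analysis: video + mask -> traces -> events -> features.

One :class:`AnalysisConfig` carries every tunable of the chain; each stage
is importable on its own, and this module only sequences them:

1. per-ROI mean traces from the label mask (:mod:`calimetry.traces`);
2. sliding-percentile baseline and dF/F0;
3. noise and AR(1) estimation, OASIS deconvolution (:mod:`calimetry.deconv`);
4. peak detection and per-ROI features (:mod:`calimetry.events`);
5. pairwise correlation (:mod:`calimetry.network`) and, when a stimulation
   protocol is present, evoked labelling and the stimulated /
   non-stimulated partition (:mod:`calimetry.evoked`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import deconv, evoked, network, traces
from .errors import EstimationError
from .events import PeakParams, RoiEvents, compute_features, detect_peaks, percent_active
from .plate import UNASSIGNED, FovRecording, PlateMap

__all__ = ["AnalysisConfig", "FovResult", "analyze_fov", "analyze_experiment",
           "feature_table"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full analysis chain."""

    baseline_window_s: float = 30.0
    baseline_percentile: float = 10.0
    noise_band: tuple[float, float] = (0.25, 0.5)
    pool_gamma_per_fov: bool = False     # median of per-ROI gamma estimates
    lam: float = 0.0
    noise_constrained: bool = False
    peaks: PeakParams = field(default_factory=PeakParams)
    evoked_window_frames: int = evoked.DEFAULT_EVOKED_WINDOW_FRAMES
    stim_epoch_window_ms: float = 250.0
    min_epoch_frames: int = network.MIN_EPOCH_FRAMES


@dataclass
class FovResult:
    """Everything computed for one field of view."""

    well_id: str
    fov_index: int
    trace_set: traces.RoiTraceSet
    deconv: list[deconv.DeconvResult]
    events: dict[int, RoiEvents]              # roi id -> events
    features: dict[int, "object"]             # roi id -> RoiFeatures
    correlation: network.CorrelationResult | None
    roi_classes: dict[str, np.ndarray] | None  # evoked partition, or None
    stim_correlation: network.CorrelationResult | None
    nonstim_correlation: network.CorrelationResult | None
    percent_active: float


def analyze_fov(rec: FovRecording, config: AnalysisConfig | None = None) -> FovResult:
    """Run the full single-FOV analysis."""
    config = config or AnalysisConfig()
    video = rec.get_video()
    if rec.label_mask is None:
        raise ValueError(f"{rec.well_id}/fov{rec.fov_index:03d}: no label mask")
    tset = traces.extract_traces(video, rec.label_mask)
    window = max(1, int(round(config.baseline_window_s * rec.frame_rate_hz)))
    tset = traces.add_dff(tset, window, config.baseline_percentile)

    # --- per-ROI noise / AR(1) / deconvolution
    sigmas, gammas = [], []
    for i in range(tset.n_rois):
        y = tset.dff[i]
        try:
            sigma = deconv.estimate_noise(y, config.noise_band)
        except EstimationError:
            sigma = float(np.std(tset.dff))  # global fallback for short traces
        sigmas.append(sigma)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gammas.append(deconv.estimate_ar_coeff(y, sigma))
        except EstimationError:
            gammas.append(0.0)
    if config.pool_gamma_per_fov and gammas:
        pooled = float(np.median(gammas))
        gammas = [pooled] * len(gammas)

    results = []
    events: dict[int, RoiEvents] = {}
    feats: dict[int, object] = {}
    for i, rid in enumerate(tset.roi_ids):
        res = deconv.deconvolve_trace(
            tset.dff[i], gamma=gammas[i], sigma=sigmas[i],
            lam=config.lam, noise_constrained=config.noise_constrained,
        )
        results.append(res)
        ev = detect_peaks(res.denoised, res.sigma, config.peaks)
        if rec.stim is not None:
            ev = evoked.match_peaks_to_pulses(
                ev, rec.stim.pulse_onset_frames, config.evoked_window_frames
            )
        events[int(rid)] = ev
        feats[int(rid)] = compute_features(
            ev, int(tset.roi_areas_px[i]), rec.pixel_size_um,
            tset.n_frames, rec.frame_rate_hz,
        )

    # --- network correlation (full recording and, if stimulated, epochs)
    roi_classes = None
    corr = stim_corr = nonstim_corr = None
    denoised = np.array([r.denoised for r in results])
    stim_flags = None
    if rec.stim is not None and rec.stim.stim_mask is not None:
        roi_classes = evoked.classify_rois(rec.label_mask, rec.stim.stim_mask)
        stim_ids = set(int(i) for i in roi_classes["stimulated"])
        stim_flags = np.array([int(r) in stim_ids for r in tset.roi_ids])
    if tset.n_rois >= 2:
        corr = network.correlation_matrix(
            denoised, roi_ids=tset.roi_ids, stim_flags=stim_flags
        )
        if rec.stim is not None and rec.stim.n_pulses > 0:
            mask = network.build_stim_frame_mask(
                rec.stim.pulse_onset_frames, config.stim_epoch_window_ms,
                rec.frame_rate_hz, tset.n_frames,
            )
            try:
                stim_corr = network.correlation_matrix(
                    denoised, roi_ids=tset.roi_ids, frame_mask=mask,
                    stim_flags=stim_flags, min_frames=config.min_epoch_frames,
                )
                nonstim_corr = network.correlation_matrix(
                    denoised, roi_ids=tset.roi_ids, frame_mask=~mask,
                    stim_flags=stim_flags, min_frames=config.min_epoch_frames,
                )
            except network.EpochError:
                pass

    return FovResult(
        well_id=rec.well_id,
        fov_index=rec.fov_index,
        trace_set=tset,
        deconv=results,
        events=events,
        features=feats,
        correlation=corr,
        roi_classes=roi_classes,
        stim_correlation=stim_corr,
        nonstim_correlation=nonstim_corr,
        percent_active=percent_active(list(feats.values())),
    )


def feature_table(
    results: list[FovResult], plate_map: PlateMap | None = None
) -> pd.DataFrame:
    """Long per-ROI feature table with condition labels from the plate map."""
    rows = []
    for res in results:
        cond = (
            plate_map.condition_label(res.well_id)
            if plate_map is not None
            else UNASSIGNED
        )
        for rid, f in res.features.items():
            rows.append(
                {
                    "well": res.well_id,
                    "fov": res.fov_index,
                    "roi": rid,
                    "condition": cond,
                    "n_events": f.n_events,
                    "event_frequency_hz": f.event_frequency_hz,
                    "mean_iei_s": f.mean_iei_s,
                    "amplitude_mean": f.amplitude_mean,
                    "amplitude_median": f.amplitude_median,
                    "cell_size_px": f.cell_size_px,
                    "cell_size_um2": f.cell_size_um2,
                    "active": f.active,
                }
            )
    return pd.DataFrame(rows)


def analyze_experiment(
    recordings: list[FovRecording],
    plate_map: PlateMap | None = None,
    config: AnalysisConfig | None = None,
) -> tuple[list[FovResult], pd.DataFrame]:
    """Analyze every FOV and assemble the combined feature table."""
    results = [analyze_fov(rec, config) for rec in recordings]
    return results, feature_table(results, plate_map)
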