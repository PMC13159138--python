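"""Per-ROI trace extraction and dF/F0 computation.

Fluorescence traces are extracted from a ``T x Y x X`` video as the arithmetic
mean over the pixels of each labelled ROI.  The baseline ``F0`` is a sliding
low-percentile of the raw trace: for each frame ``t`` the window of
``window_frames`` frames centred on ``t`` (for even lengths the extra frame
falls on the left) is clipped to the recording and the requested percentile
(default the 10th) is taken with linear interpolation between order
statistics, i.e. rank ``p/100 * (n - 1)``.  The normalized trace is

    dF/F0 = (F - F0) / F0

computed elementwise.  ROIs whose baseline falls below a positive floor are
excluded rather than aborting the whole field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BaselineError, DataError, FormatError

__all__ = [
    "RoiTraceSet",
    "extract_traces",
    "compute_baseline",
    "compute_dff",
    "add_dff",
    "DEFAULT_PERCENTILE",
]

DEFAULT_PERCENTILE = 10.0


@dataclass
class RoiTraceSet:
    """Traces for all ROIs of one field of view.

    ``raw``, ``f0`` and ``dff`` are ``N x T`` float arrays; ``f0``/``dff``
    are ``None`` until :func:`add_dff` has run.  ``excluded`` lists ROI ids
    dropped because their baseline hit the floor.
    """

    roi_ids: np.ndarray           # (N,) positive int labels, ascending
    raw: np.ndarray               # (N, T) mean fluorescence, counts
    roi_areas_px: np.ndarray      # (N,) pixel counts
    f0: np.ndarray | None = None  # (N, T) baseline, counts
    dff: np.ndarray | None = None  # (N, T) dimensionless
    excluded: list[int] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def n_frames(self) -> int:
        return self.raw.shape[1]


def extract_traces(video: np.ndarray, label_mask: np.ndarray) -> RoiTraceSet:
    """Mean-over-pixels raw trace and pixel area for every labelled ROI.

    Labels need not be contiguous; ROI order is ascending label.  Label 0 is
    background.
    """
    video = np.asarray(video)
    label_mask = np.asarray(label_mask)
    if video.ndim != 3:
        raise FormatError(f"video must be T x Y x X, got shape {video.shape}")
    if label_mask.shape != video.shape[1:]:
        raise FormatError(
            f"label mask shape {label_mask.shape} does not match "
            f"video frame shape {video.shape[1:]}"
        )
    ids = np.unique(label_mask)
    ids = ids[ids > 0]
    T = video.shape[0]
    flat_mask = label_mask.ravel()
    video2d = video.reshape(T, -1)
    raw = np.empty((len(ids), T), dtype=np.float64)
    areas = np.empty(len(ids), dtype=np.int64)
    for i, lab in enumerate(ids):
        idx = np.flatnonzero(flat_mask == lab)
        if idx.size == 0:  # pragma: no cover - unreachable after np.unique
            raise FormatError(f"ROI {lab} has no pixels")
        raw[i] = video2d[:, idx].mean(axis=1)
        areas[i] = idx.size
    return RoiTraceSet(roi_ids=ids.astype(np.int64), raw=raw, roi_areas_px=areas)


def _check_finite(trace: np.ndarray) -> None:
    bad = np.flatnonzero(~np.isfinite(trace))
    if bad.size:
        raise DataError(f"non-finite values at frames {bad[:10].tolist()}"
                        + ("..." if bad.size > 10 else ""))


def compute_baseline(
    raw: np.ndarray,
    window_frames: int,
    percentile: float = DEFAULT_PERCENTILE,
) -> np.ndarray:
    """Sliding-window percentile baseline of a single trace.

    The window centred on frame ``t`` spans ``[t - w//2, t + (w-1)//2]``
    and is clipped to ``[0, T-1]``; edge windows therefore shrink rather
    than reflect or pad.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 1 or raw.size < 1:
        raise DataError("trace must be a non-empty 1-D array")
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    _check_finite(raw)
    T = raw.size
    w = int(window_frames)
    left = w // 2
    right = (w - 1) // 2
    f0 = np.empty(T, dtype=np.float64)
    for t in range(T):
        lo = max(0, t - left)
        hi = min(T, t + right + 1)
        f0[t] = np.percentile(raw[lo:hi], percentile)
    return f0


def compute_dff(
    raw: np.ndarray,
    window_frames: int,
    percentile: float = DEFAULT_PERCENTILE,
    eps: float = 1e-12,
) -> np.ndarray:
    """dF/F0 of a single trace; raises BaselineError if F0 <= eps anywhere."""
    f0 = compute_baseline(raw, window_frames, percentile)
    if np.any(f0 <= eps):
        frame = int(np.argmax(f0 <= eps))
        raise BaselineError(
            f"baseline <= {eps:g} at frame {frame}; ROI should be excluded"
        )
    return (np.asarray(raw, dtype=np.float64) - f0) / f0


def add_dff(
    traces: RoiTraceSet,
    window_frames: int,
    percentile: float = DEFAULT_PERCENTILE,
    eps: float | None = None,
) -> RoiTraceSet:
    """Fill ``f0`` and ``dff`` for every ROI, excluding dark ROIs.

    ``eps`` defaults to ``1e-6 *`` the median raw intensity across all ROIs
    and frames; ROIs whose baseline dips below it are dropped from the set
    (ids recorded in ``excluded``) instead of failing the field of view.
    """
    if eps is None:
        med = float(np.median(traces.raw)) if traces.raw.size else 0.0
        eps = max(1e-6 * med, 1e-12)
    keep: list[int] = []
    excluded: list[int] = []
    f0 = np.empty_like(traces.raw)
    for i in range(traces.n_rois):
        f0[i] = compute_baseline(traces.raw[i], window_frames, percentile)
        if np.any(f0[i] <= eps):
            excluded.append(int(traces.roi_ids[i]))
        else:
            keep.append(i)
    keep_idx = np.array(keep, dtype=np.intp)
    raw = traces.raw[keep_idx]
    f0 = f0[keep_idx]
    return RoiTraceSet(
        roi_ids=traces.roi_ids[keep_idx],
        raw=raw,
        roi_areas_px=traces.roi_areas_px[keep_idx],
        f0=f0,
        dff=(raw - f0) / f0,
        excluded=excluded,
    )
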