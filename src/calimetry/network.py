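"""Pairwise Pearson correlation of denoised dF/F traces.

Correlation is computed between every pair of ROIs in a field of view,
either over the full recording or restricted to an epoch given as a boolean
frame mask (e.g. stimulation windows of +/-250 ms around each pulse, or
their complement).  Summary medians are taken over the upper-triangle
off-diagonal entries; when ROIs carry stimulated / non-stimulated labels the
matrix is sorted stimulated-first and within-group medians are reported from
the corresponding diagonal blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EpochError

__all__ = [
    "CorrelationResult",
    "correlation_matrix",
    "build_stim_frame_mask",
    "save_heatmap",
]

MIN_EPOCH_FRAMES = 10


@dataclass
class CorrelationResult:
    matrix: np.ndarray            # (M, M) symmetric, unit diagonal
    roi_order: np.ndarray         # ROI ids, stimulated-first when grouped
    stim_flags: np.ndarray | None  # bool per retained ROI, or None
    excluded: list[int]           # zero-variance ROI ids over the selection
    frames_used: int
    median_all: float
    median_stim_group: float       # nan when no grouping
    median_nonstim_group: float


def _upper_median(mat: np.ndarray) -> float:
    n = mat.shape[0]
    if n < 2:
        return float("nan")
    iu = np.triu_indices(n, k=1)
    return float(np.median(mat[iu]))


def correlation_matrix(
    denoised: np.ndarray,
    roi_ids: np.ndarray | None = None,
    frame_mask: np.ndarray | None = None,
    stim_flags: np.ndarray | None = None,
    min_frames: int = MIN_EPOCH_FRAMES,
) -> CorrelationResult:
    """Pearson correlation over the selected frames.

    Zero-variance ROIs (over the selection) are excluded and listed; fewer
    than two surviving ROIs leaves the medians undefined (nan).  When
    ``stim_flags`` is given, rows are reordered stimulated-first and the
    group medians come from the within-group blocks only.
    """
    X = np.asarray(denoised, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("denoised must be N x T with N >= 2")
    n, T = X.shape
    ids = np.arange(1, n + 1) if roi_ids is None else np.asarray(roi_ids)
    if frame_mask is not None:
        frame_mask = np.asarray(frame_mask, dtype=bool)
        if frame_mask.shape != (T,):
            raise ValueError("frame_mask must have one entry per frame")
        if frame_mask.sum() < min_frames:
            raise EpochError(
                f"only {int(frame_mask.sum())} frames selected; "
                f"need >= {min_frames}"
            )
        X = X[:, frame_mask]
    frames_used = X.shape[1]

    keep = np.ptp(X, axis=1) > 0  # zero variance <=> all values equal
    excluded = [int(i) for i in ids[~keep]]
    X = X[keep]
    ids = ids[keep]
    flags = None if stim_flags is None else np.asarray(stim_flags, dtype=bool)[keep]

    if flags is not None:
        order = np.argsort(~flags, kind="stable")  # stimulated first
        X, ids, flags = X[order], ids[order], flags[order]

    if X.shape[0] < 2:
        empty = np.ones((X.shape[0], X.shape[0]))
        return CorrelationResult(empty, ids, flags, excluded, frames_used,
                                 float("nan"), float("nan"), float("nan"))
    mat = np.corrcoef(X)
    med_all = _upper_median(mat)
    med_stim = med_non = float("nan")
    if flags is not None:
        ns = int(flags.sum())
        if ns >= 2:
            med_stim = _upper_median(mat[:ns, :ns])
        if X.shape[0] - ns >= 2:
            med_non = _upper_median(mat[ns:, ns:])
    return CorrelationResult(mat, ids, flags, excluded, frames_used,
                             med_all, med_stim, med_non)


def build_stim_frame_mask(
    pulse_frames: np.ndarray,
    window_ms: float,
    frame_rate_hz: float,
    n_frames: int,
) -> np.ndarray:
    """Boolean mask of frames within +/-window_ms of any pulse onset.

    The half-window in frames is ``ceil(window_ms / 1000 * frame_rate_hz)``
    (rounded up so a stimulus-adjacent frame is never dropped); windows are
    clipped to the recording and overlapping windows merge.  The complement
    of the returned mask is the non-stimulation epoch.
    """
    if window_ms < 0:
        raise ValueError("window_ms must be >= 0")
    half = math.ceil(window_ms / 1000.0 * frame_rate_hz)
    mask = np.zeros(n_frames, dtype=bool)
    for p in np.asarray(pulse_frames, dtype=np.int64):
        if not 0 <= p < n_frames:
            raise ValueError(f"pulse frame {p} outside [0, {n_frames})")
        mask[max(0, p - half) : min(n_frames, p + half + 1)] = True
    return mask


def save_heatmap(result: CorrelationResult, path) -> None:
    """Write the correlation matrix as a PNG heatmap (stim-first order)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(result.matrix, vmin=-1, vmax=1, cmap="coolwarm")
    fig.colorbar(im, ax=ax, label="Pearson r")
    if result.stim_flags is not None and result.stim_flags.any():
        ns = int(result.stim_flags.sum())
        ax.axhline(ns - 0.5, color="k", lw=0.8)
        ax.axvline(ns - 0.5, color="k", lw=0.8)
    ax.set_xlabel("ROI")
    ax.set_ylabel("ROI")
    ax.set_title(f"median r = {result.median_all:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
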