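"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by the most transparent method available
(per-frame sorting, exhaustive enumeration, linear scan) and is kept
deliberately separate from the library code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def baseline_oracle(raw, window_frames, percentile):
    """Per-frame sort + linear interpolation at rank p/100 * (n-1)."""
    raw = list(map(float, raw))
    T = len(raw)
    w = window_frames
    out = []
    for t in range(T):
        lo = max(0, t - w // 2)
        hi = min(T, t + (w - 1) // 2 + 1)
        vals = sorted(raw[lo:hi])
        n = len(vals)
        rank = percentile / 100.0 * (n - 1)
        k = int(math.floor(rank))
        frac = rank - k
        v = vals[k] if k == n - 1 else vals[k] * (1 - frac) + vals[k + 1] * frac
        out.append(v)
    return np.array(out)


def qp_oracle(y, gamma, lam):
    """Exhaustive active-set solution of the AR(1) deconvolution QP.

    minimize 1/2 ||K s - y||^2 + lam * sum(s)  s.t. s >= 0,
    where c = K s and K[t, k] = gamma^(t-k) for t >= k.  Every pattern of
    active constraints (s_t = 0) is enumerated; the feasible solution with
    the smallest objective is the optimum of the convex program.
    """
    y = np.asarray(y, dtype=float)
    T = y.size
    idx = np.arange(T)
    expo = np.subtract.outer(idx, idx)
    K = np.where(expo >= 0, float(gamma) ** np.maximum(expo, 0), 0.0)
    if gamma == 0.0:
        K = np.eye(T)
    best_obj, best_c, best_s = np.inf, None, None
    for bits in range(2**T):
        free = [t for t in range(T) if not (bits >> t) & 1]
        s = np.zeros(T)
        if free:
            B = K[:, free]
            x = np.linalg.solve(B.T @ B, B.T @ y - lam)
            if np.any(x < -1e-9):
                continue
            s[free] = np.maximum(x, 0.0)
        c = K @ s
        obj = 0.5 * np.sum((c - y) ** 2) + lam * np.sum(s)
        if obj < best_obj - 1e-15:
            best_obj, best_c, best_s = obj, c, s
    return best_c, best_s, best_obj


def peak_oracle(x, sigma, height_mode, height_value, prom_mult, min_distance):
    """Exhaustive reference peak detector.

    Scans every frame for a strict local maximum (plateaus at their first
    frame), applies height and topographic-prominence thresholds, then a
    greedy distance filter keeping the higher peak (earlier frame on ties).
    """
    x = np.asarray(x, dtype=float)
    T = x.size
    cands = []
    for left in range(1, T - 1):
        if x[left] <= x[left - 1]:
            continue
        right = left
        while right + 1 < T and x[right + 1] == x[left]:
            right += 1
        if right + 1 < T and x[right + 1] < x[left]:
            cands.append(left)
    height = height_value * sigma if height_mode == "noise_multiplier" else height_value
    cands = [c for c in cands if x[c] >= height]
    if prom_mult > 0 and sigma > 0:
        thresh = prom_mult * sigma
        cands = [c for c in cands if _prominence(x, c) >= thresh]
    kept = []
    for c in sorted(cands, key=lambda c: (-x[c], c)):
        if all(abs(c - k) >= min_distance for k in kept):
            kept.append(c)
    return sorted(kept)


def _prominence(x, peak):
    """Topographic prominence, unlimited window (scipy's definition)."""
    T = x.size
    left_min = x[peak]
    i = peak - 1
    while i >= 0 and x[i] <= x[peak]:
        left_min = min(left_min, x[i])
        i -= 1
    left_base = left_min if i >= 0 else min(left_min, x[: peak + 1].min())
    right_min = x[peak]
    i = peak + 1
    while i < T and x[i] <= x[peak]:
        right_min = min(right_min, x[i])
        i += 1
    right_base = right_min if i < T else min(right_min, x[peak:].min())
    return x[peak] - max(left_base, right_base)


def evoked_match_oracle(peak_frames, onsets, window):
    """Linear scan over all (peak, pulse) pairs; latest qualifying pulse."""
    labels, pulse_idx = [], []
    for f in peak_frames:
        match = -1
        for j, p in enumerate(onsets):
            if p <= f <= p + window - 1:
                match = j
        labels.append(match >= 0)
        pulse_idx.append(match)
    return np.array(labels, dtype=bool), np.array(pulse_idx)
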