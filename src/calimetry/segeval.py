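"""Instance-segmentation evaluation: Dice, PQ, SoftPQ, mAP.

All metrics compare a predicted integer label mask against a reference
mask of the same shape.  Conventions, stated once and tested:

* **Dice** is binary-foreground: ``2 |P & R| / (|P| + |R|)`` over nonzero
  pixels; instance-averaged Dice is available behind a flag.
* **Matching** pairs instances with IoU strictly above a threshold.  At
  thresholds >= 0.5 the matching is provably one-to-one; below 0.5 a
  greedy pass in descending IoU assigns each id at most once.
* **PQ** = sum of matched IoU / (TP + FP/2 + FN/2) at threshold 0.5, with
  the usual SQ (mean matched IoU) and RQ (detection F-ish) factorization.
* **SoftPQ** extends PQ with partial credit: pairs with IoU in
  ``(low, high]`` become partial matches (predictions single-use,
  references reusable, so fragmented references are credited); each
  contributes ``sqrt(IoU * high)`` to the numerator — the geometric mean
  of its IoU and the hard threshold, sublinear in IoU and continuous with
  the full-match credit at IoU = high — and one unit to the denominator
  while leaving FP/FN counts.  With ``low == high`` it reduces to PQ
  bit-exactly.
* **mAP** is the score-free single-class convention used for label masks:
  AP(tau) = TP / (TP + FP + FN) at each IoU threshold, averaged over
  0.50, 0.55, ..., 0.95.
* Two empty masks compare as perfect (every score 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "SegEvalPair",
    "SegScores",
    "dice",
    "match_instances",
    "panoptic_quality",
    "soft_pq",
    "mean_average_precision",
    "score_pair",
    "evaluate_set",
    "DEFAULT_MAP_THRESHOLDS",
]

DEFAULT_MAP_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass
class SegEvalPair:
    """One predicted/reference mask pair with its instance matching."""

    matches: list[tuple[int, int, float]]  # (pred_id, ref_id, IoU)
    fp_ids: np.ndarray
    fn_ids: np.ndarray
    iou_threshold: float

    @property
    def n_tp(self) -> int:
        return len(self.matches)


@dataclass
class SegScores:
    dice: float
    pq: float
    soft_pq: float
    map: float


def _check_shapes(pred: np.ndarray, ref: np.ndarray) -> None:
    if pred.shape != ref.shape:
        raise FormatError(
            f"mask shapes differ: pred {pred.shape} vs ref {ref.shape}"
        )


def dice(pred: np.ndarray, ref: np.ndarray, instance_mean: bool = False) -> float:
    """Region-overlap Dice; 1.0 when both masks are empty."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    _check_shapes(pred, ref)
    if instance_mean:
        return _instance_mean_dice(pred, ref)
    p = pred > 0
    r = ref > 0
    denom = int(p.sum()) + int(r.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & r).sum()) / denom


def _instance_mean_dice(pred: np.ndarray, ref: np.ndarray) -> float:
    pair = match_instances(pred, ref, 0.5)
    ious = np.array([iou for _, _, iou in pair.matches])
    if ious.size == 0:
        return 1.0 if (pred.max() == 0 and ref.max() == 0) else 0.0
    return float(np.mean(2 * ious / (1 + ious)))


def _pair_ious(pred: np.ndarray, ref: np.ndarray):
    """All overlapping (pred_id, ref_id) pairs with their IoU."""
    pred = np.asarray(pred).ravel()
    ref = np.asarray(ref).ravel()
    pred_ids, pred_inv = np.unique(pred, return_inverse=True)
    ref_ids, ref_inv = np.unique(ref, return_inverse=True)
    joint = np.zeros((len(pred_ids), len(ref_ids)), dtype=np.int64)
    np.add.at(joint, (pred_inv, ref_inv), 1)
    pred_area = joint.sum(axis=1)
    ref_area = joint.sum(axis=0)
    pairs = []
    for i, pid in enumerate(pred_ids):
        if pid == 0:
            continue
        for j, rid in enumerate(ref_ids):
            if rid == 0 or joint[i, j] == 0:
                continue
            inter = joint[i, j]
            union = pred_area[i] + ref_area[j] - inter
            pairs.append((int(pid), int(rid), inter / union))
    fg_pred = pred_ids[pred_ids > 0]
    fg_ref = ref_ids[ref_ids > 0]
    return pairs, fg_pred, fg_ref


def match_instances(
    pred: np.ndarray, ref: np.ndarray, iou_threshold: float = 0.5
) -> SegEvalPair:
    """Match instances at IoU > threshold (greedy descending IoU).

    At thresholds >= 0.5 the greedy pass is equivalent to the unique
    one-to-one matching, since no instance can have IoU > 0.5 with two
    disjoint partners.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    _check_shapes(pred, ref)
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must be in (0, 1)")
    pairs, fg_pred, fg_ref = _pair_ious(pred, ref)
    pairs = [p for p in pairs if p[2] > iou_threshold]
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    used_p: set[int] = set()
    used_r: set[int] = set()
    matches = []
    for pid, rid, iou in pairs:
        if pid in used_p or rid in used_r:
            continue
        used_p.add(pid)
        used_r.add(rid)
        matches.append((pid, rid, iou))
    fp = np.array([p for p in fg_pred if p not in used_p], dtype=np.int64)
    fn = np.array([r for r in fg_ref if r not in used_r], dtype=np.int64)
    return SegEvalPair(matches=matches, fp_ids=fp, fn_ids=fn,
                       iou_threshold=iou_threshold)


def panoptic_quality(pair: SegEvalPair) -> tuple[float, float, float]:
    """(PQ, SQ, RQ) from a matching done at threshold 0.5.

    PQ = sum IoU / (TP + FP/2 + FN/2); no instances at all gives 1.0.
    """
    tp = pair.n_tp
    fp = len(pair.fp_ids)
    fn = len(pair.fn_ids)
    if tp + fp + fn == 0:
        return 1.0, 1.0, 1.0
    denom = tp + 0.5 * fp + 0.5 * fn
    iou_sum = sum(iou for _, _, iou in pair.matches)
    pq = iou_sum / denom
    sq = iou_sum / tp if tp else 0.0
    rq = tp / denom
    return float(pq), float(sq), float(rq)


def soft_pq(
    pred: np.ndarray,
    ref: np.ndarray,
    low_threshold: float = 0.05,
    high_threshold: float = 0.5,
) -> float:
    """PQ with sublinear partial credit for overlaps in (low, high].

    Full matches (IoU > high, one-to-one) contribute their IoU as in PQ.
    Remaining pairs with IoU > low become partial matches — predictions
    used once, references reusable — contributing ``sqrt(IoU * high)`` to
    the numerator and a full unit to the denominator; leftover instances
    count as FP/FN with weight 1/2.  ``low == high`` reproduces PQ exactly.
    """
    if not 0.0 < low_threshold <= high_threshold <= 0.5:
        raise ValueError("need 0 < low <= high <= 0.5")
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    _check_shapes(pred, ref)
    pairs, fg_pred, fg_ref = _pair_ious(pred, ref)
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    used_p: set[int] = set()
    full_r: set[int] = set()
    touched_r: set[int] = set()
    numerator = 0.0
    n_units = 0
    for pid, rid, iou in pairs:
        if iou > high_threshold:
            if pid in used_p or rid in full_r or rid in touched_r:
                continue
            used_p.add(pid)
            full_r.add(rid)
            touched_r.add(rid)
            numerator += iou
            n_units += 1
    for pid, rid, iou in pairs:
        if low_threshold < iou <= high_threshold:
            if pid in used_p or rid in full_r:
                continue
            used_p.add(pid)
            touched_r.add(rid)
            numerator += np.sqrt(iou * high_threshold)
            n_units += 1
    fp = sum(1 for p in fg_pred if p not in used_p)
    fn = sum(1 for r in fg_ref if r not in touched_r)
    if n_units + fp + fn == 0:
        return 1.0
    return float(numerator / (n_units + 0.5 * fp + 0.5 * fn))


def mean_average_precision(
    pred: np.ndarray,
    ref: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_MAP_THRESHOLDS,
) -> float:
    """Mean over IoU thresholds of AP = TP / (TP + FP + FN)."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    _check_shapes(pred, ref)
    if pred.max() == 0 and ref.max() == 0:
        return 1.0
    aps = []
    for tau in thresholds:
        pair = match_instances(pred, ref, float(tau))
        tp = pair.n_tp
        aps.append(tp / (tp + len(pair.fp_ids) + len(pair.fn_ids)))
    return float(np.mean(aps))


def score_pair(pred: np.ndarray, ref: np.ndarray) -> SegScores:
    """All four metrics for one mask pair at their default settings."""
    pair = match_instances(pred, ref, 0.5)
    pq, _, _ = panoptic_quality(pair)
    return SegScores(
        dice=dice(pred, ref),
        pq=pq,
        soft_pq=soft_pq(pred, ref),
        map=mean_average_precision(pred, ref),
    )


def evaluate_set(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-image scores plus a summary row of mean and population SD.

    The returned frame has one row per image and two trailing rows
    ``mean`` / ``sd`` (population SD, ddof=0; a single image reports 0).
    """
    if not pairs:
        raise ValueError("need at least one mask pair")
    names = names or [f"image_{i:03d}" for i in range(len(pairs))]
    rows = []
    for name, (pred, ref) in zip(names, pairs):
        s = score_pair(pred, ref)
        rows.append({"image": name, "dice": s.dice, "pq": s.pq,
                     "soft_pq": s.soft_pq, "map": s.map})
    df = pd.DataFrame(rows)
    cols = ["dice", "pq", "soft_pq", "map"]
    mean = df[cols].mean()
    sd = df[cols].std(ddof=0)
    df = pd.concat(
        [df,
         pd.DataFrame([{"image": "mean", **mean.to_dict()},
                       {"image": "sd", **sd.to_dict()}])],
        ignore_index=True,
    )
    return df
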