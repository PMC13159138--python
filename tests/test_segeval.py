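"""Instance-segmentation metrics on hand-constructed fixtures."""

import numpy as np
import pytest

from calimetry.errors import FormatError
from calimetry.segeval import (
    dice,
    evaluate_set,
    match_instances,
    mean_average_precision,
    panoptic_quality,
    score_pair,
    soft_pq,
)


def _three_instance_mask():
    m = np.zeros((12, 12), dtype=np.int32)
    m[1:4, 1:4] = 1
    m[6:9, 2:5] = 2
    m[2:5, 7:11] = 3
    return m


class TestDice:
    def test_identical_masks(self):
        m = _three_instance_mask()
        assert dice(m, m) == 1.0

    def test_disjoint_foregrounds(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0, 0], b[3, 3] = 1, 1
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0, 0:4] = 1          # 4 px
        b[0, 2:4] = 1
        b[1, 0:2] = 1          # 4 px, overlap 2
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3), dtype=int)
        assert dice(z, z) == 1.0


class TestMatching:
    def test_perfect_match(self):
        m = _three_instance_mask()
        pair = match_instances(m, m, 0.5)
        assert pair.n_tp == 3
        assert len(pair.fp_ids) == 0 and len(pair.fn_ids) == 0

    def test_iou06_matched_at_05_not_065(self, iou06_masks):
        pred, ref = iou06_masks
        pair = match_instances(pred, ref, 0.5)
        assert pair.n_tp == 1
        assert pair.matches[0][2] == pytest.approx(0.6)
        pair = match_instances(pred, ref, 0.65)
        assert pair.n_tp == 0
        assert len(pair.fp_ids) == 1 and len(pair.fn_ids) == 1

    def test_hard_threshold_matching_is_unique(self, rng):
        """At IoU > 0.5 greedy matching equals exhaustive optimal assignment."""
        from itertools import permutations

        for _ in range(30):
            pred = rng.integers(0, 4, (8, 8)).astype(np.int32)
            ref = rng.integers(0, 4, (8, 8)).astype(np.int32)
            pair = match_instances(pred, ref, 0.5)
            got = {(p, r) for p, r, _ in pair.matches}
            # exhaustive: best one-to-one assignment above threshold
            from calimetry.segeval import _pair_ious

            pairs, fg_p, fg_r = _pair_ious(pred, ref)
            above = [(p, r) for p, r, iou in pairs if iou > 0.5]
            assert got == set(above)  # uniqueness: all qualifying pairs kept


class TestPQ:
    def test_perfect(self):
        m = _three_instance_mask()
        pq, sq, rq = panoptic_quality(match_instances(m, m, 0.5))
        assert pq == sq == rq == 1.0

    def test_single_tp(self, iou06_masks):
        pred, ref = iou06_masks
        pq, _, _ = panoptic_quality(match_instances(pred, ref, 0.5))
        assert pq == pytest.approx(0.6)

    def test_tp_plus_fp(self, iou06_masks):
        pred, ref = iou06_masks
        pred = pred.copy()
        pred[4:6, 5:8] = 2  # spurious detection far from ref
        pq, sq, rq = panoptic_quality(match_instances(pred, ref, 0.5))
        assert pq == pytest.approx(0.6 / 1.5)  # 0.4
        assert sq == pytest.approx(0.6)
        assert pq == pytest.approx(sq * rq)

    def test_empty_vs_empty_is_one(self):
        z = np.zeros((4, 4), dtype=int)
        assert panoptic_quality(match_instances(z, z, 0.5))[0] == 1.0


class TestSoftPQ:
    def test_perfect_equals_one(self):
        m = _three_instance_mask()
        assert soft_pq(m, m) == 1.0

    def test_reduces_to_pq_when_low_equals_high(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 5, (10, 10)).astype(np.int32)
            ref = rng.integers(0, 5, (10, 10)).astype(np.int32)
            pq, _, _ = panoptic_quality(match_instances(pred, ref, 0.5))
            assert soft_pq(pred, ref, 0.5, 0.5) == pq  # bit-exact

    def test_undersegmentation_gets_partial_credit(self):
        # one reference object split into two predictions, IoU 0.4 each
        ref = np.zeros((4, 10), dtype=np.int32)
        ref[:, 1:9] = 1          # 32 px
        pred = np.zeros_like(ref)
        pred[:, 0:4] = 1         # 16 px, overlap 12 -> IoU 12/36 > 0.3
        pred[:, 5:9] = 2         # 16 px, overlap 16/32 = 0.5
        pq, _, _ = panoptic_quality(match_instances(pred, ref, 0.5))
        spq = soft_pq(pred, ref)
        assert spq > pq

    def test_scores_within_unit_interval(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 6, (12, 12)).astype(np.int32)
            ref = rng.integers(0, 6, (12, 12)).astype(np.int32)
            assert 0.0 <= soft_pq(pred, ref) <= 1.0


class TestMap:
    def test_perfect(self):
        m = _three_instance_mask()
        assert mean_average_precision(m, m) == 1.0

    def test_single_pair_iou_055(self):
        # pred 10 px, ref 12 px, overlap 8 -> IoU 8/14 ~ 0.571 > 0.55 only
        # build IoU in (0.55, 0.60): inter 8, union 14
        pred = np.zeros((4, 8), dtype=np.int32)
        ref = np.zeros((4, 8), dtype=np.int32)
        pred[0:2, 0:5] = 1          # 10 px
        ref[0:3, 1:5] = 1           # 12 px; inter rows 0-1 cols 1-4 = 8
        iou = 8 / 14
        assert 0.55 < iou < 0.60
        got = mean_average_precision(pred, ref)
        assert got == pytest.approx(0.2)  # TPs at tau = 0.50 and 0.55

    def test_single_pair_exceeding_only_first_threshold(self):
        # IoU in (0.50, 0.55]: inter 6, union 11 -> 0.545
        pred = np.zeros((4, 8), dtype=np.int32)
        ref = np.zeros((4, 8), dtype=np.int32)
        pred[0, 0:6] = 1                    # 6 px
        pred[1, 0:2] = 1                    # +2 = 8 px
        ref[0, 0:6] = 1
        ref[1, 4:7] = 1                     # 9 px; inter = 6
        iou = 6 / 11
        assert 0.50 < iou <= 0.55
        assert mean_average_precision(pred, ref) == pytest.approx(0.1)

    def test_empty_pred_nonempty_ref(self):
        ref = _three_instance_mask()
        assert mean_average_precision(np.zeros_like(ref), ref) == 0.0


class TestInvariantsAndSet:
    def test_label_permutation_invariance(self, rng):
        pred = rng.integers(0, 5, (12, 12)).astype(np.int32)
        ref = rng.integers(0, 5, (12, 12)).astype(np.int32)
        perm = np.array([0, 3, 1, 4, 2])
        pred_perm = perm[pred]
        a, b = score_pair(pred, ref), score_pair(pred_perm, ref)
        assert (a.dice, a.pq, a.soft_pq, a.map) == (b.dice, b.pq, b.soft_pq, b.map)

    def test_all_one_iff_equal(self):
        m = _three_instance_mask()
        s = score_pair(m, m)
        assert s.dice == s.pq == s.soft_pq == s.map == 1.0
        m2 = m.copy()
        m2[0, 0] = 9
        s2 = score_pair(m2, m)
        assert s2.map < 1.0 or s2.pq < 1.0

    def test_evaluate_set_summary(self):
        m = _three_instance_mask()
        df = evaluate_set([(m, m)] * 3)
        mean_row = df[df["image"] == "mean"].iloc[0]
        sd_row = df[df["image"] == "sd"].iloc[0]
        assert all(mean_row[c] == 1.0 for c in ["dice", "pq", "soft_pq", "map"])
        assert all(sd_row[c] == 0.0 for c in ["dice", "pq", "soft_pq", "map"])

    def test_population_sd_convention(self):
        m = _three_instance_mask()
        z = np.zeros_like(m)
        df = evaluate_set([(m, m), (z, m)])
        # per-image dice are 1.0 and 0.0 -> mean .5, population SD .5
        assert df[df["image"] == "mean"].iloc[0]["dice"] == pytest.approx(0.5)
        assert df[df["image"] == "sd"].iloc[0]["dice"] == pytest.approx(0.5)

    def test_shape_mismatch(self):
        with pytest.raises(FormatError):
            dice(np.zeros((3, 3), dtype=int), np.zeros((4, 4), dtype=int))
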