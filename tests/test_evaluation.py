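"""Detection metrics: IoU, matching, AP interpolations, mAP, recall, AR."""

import numpy as np
import pytest

from foalwatch.boxes import iou
from foalwatch.coco import Annotation, CocoDataset, ImageRecord
from foalwatch.evaluation import (IOU_THRESHOLDS, ImageDetection, MatchCounts,
                                  PRCurve, average_precision, average_recall,
                                  match_detections, mean_ap, read_detections,
                                  recall, write_detections)

RNG = np.random.default_rng(77)


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 10, 10), (20, 20, 5, 5)) == 0.0

    def test_half_shift(self):
        assert iou((0, 0, 10, 10), (5, 0, 10, 10)) == pytest.approx(1 / 3)


class TestMatching:
    def test_single_true_positive(self):
        counts, flags = match_detections(
            [((0, 0, 10, 10), 0.9)], [(1, 1, 10, 10)], 0.5
        )
        assert (counts.TP, counts.FP, counts.FN) == (1, 0, 0)
        assert flags == [True]

    def test_double_detection_single_gt(self):
        counts, flags = match_detections(
            [((0, 0, 10, 10), 0.9), ((0.5, 0, 10, 10), 0.8)],
            [(0, 0, 10, 10)], 0.5,
        )
        assert (counts.TP, counts.FP) == (1, 1)
        assert flags == [True, False]

    def test_all_missed(self):
        counts, _ = match_detections([], [(0, 0, 5, 5)] * 3, 0.5)
        assert counts.FN == 3

    def test_tie_breaks_to_lower_gt_index(self):
        # two identical GTs: the detection must claim the first
        counts, flags = match_detections(
            [((0, 0, 10, 10), 0.9)], [(0, 0, 10, 10), (0, 0, 10, 10)], 0.5
        )
        assert counts.TP == 1 and counts.FN == 1

    def test_equal_score_order_invariance(self):
        dets_a = [((0, 0, 10, 10), 0.8), ((30, 30, 10, 10), 0.8)]
        gts = [(0, 0, 10, 10), (30, 30, 10, 10)]
        ca, _ = match_detections(dets_a, gts, 0.5)
        cb, _ = match_detections(list(reversed(dets_a)), gts, 0.5)
        assert (ca.TP, ca.FP) == (cb.TP, cb.FP) == (2, 0)


class TestAveragePrecision:
    def test_perfect_single_detection(self):
        curve = PRCurve.from_flags([True], n_pos=1)
        assert average_precision(curve) == pytest.approx(1.0)

    def test_fp_then_tp_gives_half(self):
        # ranked FP, TP on one GT: precision at full recall is 0.5; the
        # 11-point oracle takes max precision to the right of every point
        curve = PRCurve.from_flags([False, True], n_pos=1)
        brute = np.mean([
            max([p for r, p in curve.points if r >= q], default=0.0)
            for q in np.linspace(0, 1, 11)
        ])
        assert average_precision(curve) == pytest.approx(0.5)
        assert average_precision(curve) == pytest.approx(brute)

    def test_no_true_positive_is_zero(self):
        curve = PRCurve.from_flags([False, False], n_pos=2)
        assert average_precision(curve) == 0.0

    def test_undefined_without_positives(self):
        assert average_precision(PRCurve.from_flags([False], n_pos=0)) is None

    def test_trailing_zero_score_fps_do_not_change_ap(self):
        base = PRCurve.from_flags([True, True], n_pos=2)
        padded = PRCurve.from_flags([True, True, False, False], n_pos=2)
        assert average_precision(base) == average_precision(padded)

    def test_dense_curves_agree_across_interpolations(self):
        flags = list(RNG.random(300) < 0.6)
        curve = PRCurve.from_flags(flags, n_pos=int(sum(flags)))
        a = average_precision(curve, "11point")
        b = average_precision(curve, "all_points")
        assert abs(a - b) < 0.1

    def test_unknown_interpolation_rejected(self):
        with pytest.raises(ValueError):
            average_precision(PRCurve.from_flags([True], 1), "7point")


class TestRecall:
    def test_simple_ratio(self):
        assert recall(MatchCounts(TP=49, FP=0, FN=1)) == pytest.approx(0.98)

    def test_perfect_queries(self):
        qs = [MatchCounts(5, 0, 0)] * 4
        assert average_recall(qs) == 1.0

    def test_mean_of_two_queries(self):
        qs = [MatchCounts(4, 0, 0), MatchCounts(2, 0, 2)]
        assert average_recall(qs) == pytest.approx(0.75)

    def test_zero_denominator_query_skipped(self):
        qs = [MatchCounts(0, 3, 0), MatchCounts(1, 0, 1)]
        assert average_recall(qs) == pytest.approx(0.5)


def brute_force_class_ap(gts_by_img, dets, iou_thr, recall_points):
    """Exhaustive re-implementation: match per image, pool, interpolate."""
    scored = []
    n_pos = sum(len(v) for v in gts_by_img.values())
    for img, gt in gts_by_img.items():
        img_dets = sorted([d for d in dets if d[0] == img], key=lambda d: -d[2])
        taken = set()
        for _, box, score in img_dets:
            best, bi = 0.0, -1
            for j, g in enumerate(gt):
                if j in taken:
                    continue
                v = iou(box, g)
                if v >= iou_thr and v > best:
                    best, bi = v, j
            if bi >= 0:
                taken.add(bi)
            scored.append((score, bi >= 0))
    scored.sort(key=lambda t: -t[0])
    tp = fp = 0
    pts = []
    for score, flag in scored:
        tp += flag
        fp += not flag
        pts.append((tp / n_pos, tp / (tp + fp)))
    return np.mean([
        max([p for r, p in pts if r >= q], default=0.0) for q in recall_points
    ])


class TestMeanAP:
    def _fixture(self):
        images = [ImageRecord(i, f"{i}.png", 200, 200) for i in range(1, 6)]
        anns, dets = [], []
        aid = 0
        rng = np.random.default_rng(11)
        for im in images:
            for cid in (1, 2):
                for _ in range(int(rng.integers(1, 3))):
                    x, y = rng.uniform(0, 120, 2)
                    w, h = rng.uniform(20, 60, 2)
                    w = min(w, 200 - x)
                    h = min(h, 200 - y)
                    aid += 1
                    anns.append(Annotation(aid, im.id, cid, (x, y, w, h)))
                    # noisy detection near the GT plus an occasional FP
                    jx, jy = rng.uniform(-8, 8, 2)
                    dets.append(ImageDetection(
                        im.id, cid,
                        (max(x + jx, 0), max(y + jy, 0), w, h),
                        float(rng.uniform(0.3, 1.0)),
                    ))
                    if rng.random() < 0.4:
                        dets.append(ImageDetection(
                            im.id, cid, (rng.uniform(0, 150), rng.uniform(0, 150),
                                         20, 20), float(rng.uniform(0, 0.6)),
                        ))
        gts = CocoDataset(images=images, annotations=anns).validate()
        return gts, dets

    def test_perfect_detections_score_hundred(self, toy_coco):
        dets = [
            ImageDetection(a.image_id, a.category_id, tuple(a.bbox), 0.99)
            for a in toy_coco.annotations
        ]
        rep = mean_ap(toy_coco, dets)
        assert rep.mAP == pytest.approx(100.0)
        assert rep.AR == pytest.approx(100.0)

    def test_missing_class_scores_zero(self, toy_coco):
        dets = [
            ImageDetection(a.image_id, a.category_id, tuple(a.bbox), 0.9)
            for a in toy_coco.annotations if a.category_id == 1
        ]
        rep = mean_ap(toy_coco, dets)
        assert rep.mAP_MNP == 0.0
        assert rep.mAP_MP == pytest.approx(100.0)

    def test_matches_bruteforce_reference_on_fixture(self):
        gts, dets = self._fixture()
        rep = mean_ap(gts, dets)
        aps = []
        for cid in (1, 2):
            gt_by_img = {
                im.id: [a.bbox for a in gts.annotations
                        if a.image_id == im.id and a.category_id == cid]
                for im in gts.images
            }
            trip = [(d.image_id, d.bbox, d.score) for d in dets
                    if d.category_id == cid]
            for thr in IOU_THRESHOLDS:
                aps.append(brute_force_class_ap(
                    gt_by_img, trip, thr, np.linspace(0, 1, 11)))
        assert rep.mAP == pytest.approx(100 * float(np.mean(aps)), abs=1e-9)

    def test_unknown_category_rejected(self, toy_coco):
        with pytest.raises(ValueError):
            mean_ap(toy_coco, [ImageDetection(1, 9, (0, 0, 5, 5), 0.5)])

    def test_report_serialises_and_tabulates(self, toy_coco):
        dets = [
            ImageDetection(a.image_id, a.category_id, tuple(a.bbox), 0.9)
            for a in toy_coco.annotations
        ]
        rep = mean_ap(toy_coco, dets)
        d = rep.to_dict()
        assert set(d) == {"mAP", "mAP50", "mAP75", "mAP90",
                          "mAP_MP", "mAP_MNP", "AR"}
        assert "mAP50" in rep.table()


def test_detection_json_roundtrip(tmp_path):
    dets = [ImageDetection(1, 2, (1.0, 2.0, 3.0, 4.0), 0.75)]
    path = write_detections(dets, tmp_path / "dets.json")
    back = read_detections(path)
    assert back == dets
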