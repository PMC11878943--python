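"""COCO-style detection metrics: matching, AP, mAP, recall and AR.

Average precision follows the 11-point interpolation

    AP = (1/11) Σ_{r ∈ {0, 0.1, …, 1}} max{ p_i : r_i ≥ r },

the default here because it is the form the detection study reports; the
101-point COCO variant and the exact area form Σ p_i Δr_i (maximum
precision to the right of each attained recall, summed over recall
increments) are selectable.  mAP averages AP over both classes and the ten
IoU thresholds 0.50:0.05:0.95; AR averages recall over the same
thresholds.  All headline numbers are reported as percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .boxes import iou_matrix
from .coco import CATEGORY_NAMES, CocoDataset

IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
ELEVEN_POINTS = tuple(np.round(np.linspace(0.0, 1.0, 11), 1))
MAX_DETS_PER_IMAGE = 100


@dataclass
class MatchCounts:
    TP: int
    FP: int
    FN: int

    @property
    def T(self) -> int:
        return self.TP + self.FP + self.FN


@dataclass
class PRCurve:
    """Ranked precision-recall points for one class at one IoU threshold."""

    n_pos: int
    points: list[tuple[float, float]] = field(default_factory=list)  # (r_i, p_i)

    @classmethod
    def from_flags(cls, tp_flags: Sequence[bool], n_pos: int) -> "PRCurve":
        """Build the curve from score-ranked TP/FP flags."""
        pts = []
        tp = fp = 0
        for flag in tp_flags:
            tp += bool(flag)
            fp += not flag
            r = tp / n_pos if n_pos else 0.0
            pts.append((r, tp / (tp + fp)))
        return cls(n_pos=n_pos, points=pts)


@dataclass
class ImageDetection:
    image_id: int
    category_id: int
    bbox: tuple[float, float, float, float]
    score: float


@dataclass
class EvalReport:
    mAP: float
    mAP50: float
    mAP75: float
    mAP90: float
    mAP_MP: float
    mAP_MNP: float
    AR: float

    def to_dict(self) -> dict[str, float]:
        return dict(vars(self))

    def table(self) -> str:
        rows = [f"  {k:<8} {v:6.2f} %" for k, v in self.to_dict().items()]
        return "metric    value\n" + "\n".join(rows)


def match_detections(
    dets: Sequence[tuple[Sequence[float], float]],
    gts: Sequence[Sequence[float]],
    iou_thr: float,
) -> tuple[MatchCounts, list[bool]]:
    """Greedy matching on one image, one class.

    Detections are processed in descending score; each takes the unmatched
    ground truth of highest IoU provided it reaches the threshold, ties
    broken by ground-truth index.  Returns counts and the per-detection
    TP flags in the ranked order.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    matrix = iou_matrix([dets[i][0] for i in order], gts)
    matched: set[int] = set()
    flags_ranked: list[bool] = []
    for row in range(len(order)):
        best_j, best_iou = -1, -1.0
        for j in range(len(gts)):
            v = matrix[row, j]
            # strict > keeps the lowest-index GT on IoU ties
            if j not in matched and v >= iou_thr and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched.add(best_j)
            flags_ranked.append(True)
        else:
            flags_ranked.append(False)
    tp = sum(flags_ranked)
    counts = MatchCounts(TP=tp, FP=len(dets) - tp, FN=len(gts) - tp)
    return counts, flags_ranked


def average_precision(
    curve: PRCurve, interpolation: str = "11point"
) -> float | None:
    """AP of a PR curve; ``None`` (undefined) when there are no positives."""
    if curve.n_pos == 0:
        return None
    if not curve.points:
        return 0.0
    recalls = np.array([r for r, _ in curve.points])
    precisions = np.array([p for _, p in curve.points])

    def p_at(r: float) -> float:
        mask = recalls >= r - 1e-12
        return float(precisions[mask].max()) if mask.any() else 0.0

    if interpolation == "11point":
        return float(np.mean([p_at(r) for r in ELEVEN_POINTS]))
    if interpolation == "101point":
        return float(np.mean([p_at(r) for r in np.linspace(0, 1, 101)]))
    if interpolation == "all_points":
        # Σ p_i Δr_i over attained recall increments, with p_i the maximum
        # precision at recall ≥ r_i (exact area under the staircase)
        ap = 0.0
        prev_r = 0.0
        for r in sorted(set(np.round(recalls, 12))):
            if r <= prev_r:
                continue
            ap += (r - prev_r) * p_at(r)
            prev_r = r
        return float(ap)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def recall(counts: MatchCounts) -> float:
    if counts.TP + counts.FN == 0:
        raise ValueError("recall undefined without ground-truth instances")
    return counts.TP / (counts.TP + counts.FN)


def average_recall(per_query: Sequence[MatchCounts]) -> float:
    """Mean recall over a query set (here: the IoU thresholds)."""
    if not per_query:
        raise ValueError("average_recall needs at least one query")
    vals = []
    for q in per_query:
        if q.TP + q.FN == 0:
            continue  # query skipped: no positives to recall
        vals.append(q.TP / (q.TP + q.FN))
    if not vals:
        raise ValueError("all queries had zero denominators")
    return float(np.mean(vals))


def _class_eval(
    gts: CocoDataset,
    dets: Sequence[ImageDetection],
    category_id: int,
    iou_thr: float,
    interpolation: str = "11point",
    max_dets: int = MAX_DETS_PER_IMAGE,
) -> tuple[float | None, MatchCounts]:
    """AP and match counts for one class at one IoU threshold."""
    gt_by_image: dict[int, list] = {im.id: [] for im in gts.images}
    for a in gts.annotations:
        if a.category_id == category_id:
            gt_by_image[a.image_id].append(a.bbox)
    n_pos = sum(len(v) for v in gt_by_image.values())

    det_by_image: dict[int, list[ImageDetection]] = {im.id: [] for im in gts.images}
    for d in dets:
        if d.category_id == category_id:
            if d.image_id not in det_by_image:
                raise ValueError(f"detection references unknown image {d.image_id}")
            det_by_image[d.image_id].append(d)

    scored_flags: list[tuple[float, bool]] = []
    tp_total = 0
    for img_id, img_dets in det_by_image.items():
        img_dets = sorted(img_dets, key=lambda d: -d.score)[:max_dets]
        _, flags = match_detections(
            [(d.bbox, d.score) for d in img_dets], gt_by_image[img_id], iou_thr
        )
        for d, f in zip(img_dets, flags):
            scored_flags.append((d.score, f))
            tp_total += bool(f)
    scored_flags.sort(key=lambda t: -t[0])
    curve = PRCurve.from_flags([f for _, f in scored_flags], n_pos)
    counts = MatchCounts(TP=tp_total, FP=len(scored_flags) - tp_total,
                         FN=n_pos - tp_total)
    return average_precision(curve, interpolation), counts


def mean_ap(
    gts: CocoDataset,
    dets: Sequence[ImageDetection],
    iou_set: Sequence[float] = IOU_THRESHOLDS,
    interpolation: str = "11point",
    max_dets: int = MAX_DETS_PER_IMAGE,
) -> EvalReport:
    """Full evaluation report over classes × IoU thresholds, in percent."""
    known = set(gts.categories.values())
    for d in dets:
        if d.category_id not in known:
            raise ValueError(f"unknown category id {d.category_id} in detections")

    ap_table: dict[int, dict[float, float | None]] = {}
    rec_table: dict[int, dict[float, MatchCounts]] = {}
    for cid in sorted(known):
        ap_table[cid], rec_table[cid] = {}, {}
        for thr in iou_set:
            ap, counts = _class_eval(gts, dets, cid, thr, interpolation, max_dets)
            ap_table[cid][thr] = ap
            rec_table[cid][thr] = counts

    def cls_mean(thr: float) -> float:
        vals = [
            ap_table[c][thr]
            for c in ap_table
            if thr in ap_table[c] and ap_table[c][thr] is not None
        ]
        return 100.0 * float(np.mean(vals)) if vals else 0.0

    def thr_mean(cid: int) -> float:
        vals = [v for v in ap_table[cid].values() if v is not None]
        return 100.0 * float(np.mean(vals)) if vals else 0.0

    all_vals = [
        v for c in ap_table for v in ap_table[c].values() if v is not None
    ]
    ar_queries = [rec_table[c][t] for c in rec_table for t in rec_table[c]]
    from .coco import CATEGORY_IDS

    return EvalReport(
        mAP=100.0 * float(np.mean(all_vals)) if all_vals else 0.0,
        mAP50=cls_mean(0.50),
        mAP75=cls_mean(0.75),
        mAP90=cls_mean(0.90),
        mAP_MP=thr_mean(CATEGORY_IDS["MP"]),
        mAP_MNP=thr_mean(CATEGORY_IDS["MNP"]),
        AR=100.0 * average_recall(ar_queries),
    )


# -- results JSON I/O ---------------------------------------------------

def read_detections(path: str | Path) -> list[ImageDetection]:
    """COCO results format: [{image_id, category_id, bbox, score}, ...]."""
    with open(path) as fh:
        data = json.load(fh)
    return [
        ImageDetection(
            image_id=d["image_id"], category_id=d["category_id"],
            bbox=tuple(d["bbox"]), score=d["score"],
        )
        for d in data
    ]


def write_detections(dets: Sequence[ImageDetection], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(
            [
                {"image_id": d.image_id, "category_id": d.category_id,
                 "bbox": list(d.bbox), "score": d.score}
                for d in dets
            ],
            fh, indent=1,
        )
    return path
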