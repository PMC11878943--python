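"""Box primitives shared by the detector, evaluator and alert layer.

Boxes are ``(x, y, w, h)`` in pixels, 0-based, top-left origin, half-open
extents (a box covers [x, x+w) × [y, y+h)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class DetectionBox:
    x: float
    y: float
    w: float
    h: float
    score: float = 1.0
    label: str = "MNP"

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"degenerate box {self.x, self.y, self.w, self.h}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.w, self.h)


def _as_xywh(box) -> tuple[float, float, float, float]:
    if isinstance(box, DetectionBox):
        return box.bbox
    x, y, w, h = box
    return float(x), float(y), float(w), float(h)


def iou(a, b) -> float:
    """Intersection-over-union of two xywh boxes."""
    ax, ay, aw, ah = _as_xywh(a)
    bx, by, bw, bh = _as_xywh(b)
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def iou_matrix(boxes_a: Sequence, boxes_b: Sequence) -> np.ndarray:
    """Pairwise IoU, shape (len(a), len(b)); vectorised."""
    if len(boxes_a) == 0 or len(boxes_b) == 0:
        return np.zeros((len(boxes_a), len(boxes_b)))
    A = np.array([_as_xywh(b) for b in boxes_a], dtype=np.float64)
    B = np.array([_as_xywh(b) for b in boxes_b], dtype=np.float64)
    ax0, ay0 = A[:, 0:1], A[:, 1:2]
    ax1, ay1 = ax0 + A[:, 2:3], ay0 + A[:, 3:4]
    bx0, by0 = B[None, :, 0], B[None, :, 1]
    bx1, by1 = bx0 + B[None, :, 2], by0 + B[None, :, 3]
    iw = np.clip(np.minimum(ax1, bx1) - np.maximum(ax0, bx0), 0, None)
    ih = np.clip(np.minimum(ay1, by1) - np.maximum(ay0, by0), 0, None)
    inter = iw * ih
    union = A[:, 2:3] * A[:, 3:4] + B[None, :, 2] * B[None, :, 3] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def nms(boxes: Sequence, scores: Sequence[float], iou_thr: float = 0.5) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices by score order."""
    n = len(boxes)
    if n == 0:
        return []
    order = np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")
    matrix = iou_matrix(boxes, boxes)
    suppressed = np.zeros(n, dtype=bool)
    kept: list[int] = []
    for i in order:
        if suppressed[i]:
            continue
        kept.append(int(i))
        suppressed |= matrix[i] > iou_thr
    return kept
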