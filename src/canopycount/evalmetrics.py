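"""Step 5 — detection quality and counting accuracy.

Detection quality follows the COCO evaluation convention: a prediction is a
true positive at an IoU threshold t only when its overlap with an unmatched
ground-truth box strictly exceeds t; average precision uses 101-point
interpolation over recall anchors 0, 0.01, ..., 1; mAP_COCO is the mean AP
over the ten thresholds 0.50, 0.55, ..., 0.95.

Counting accuracy is the Mean Absolute Percentage Error over trays,

    MAPE% = (100 / n) * sum_i |C_pred,i - C_manual,i| / C_manual,i,

with trays whose manual count is zero excluded from the sum (the ratio is
undefined there) and reported separately as a zero-truth false-positive
count.  The complementary counting accuracy is 100 - MAPE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import BBox, DetectionSet
from .exceptions import UndefinedMetricError

__all__ = [
    "MatchResult",
    "MetricsReport",
    "iou",
    "match_detections",
    "precision_recall",
    "average_precision",
    "map_coco",
    "count_plants",
    "mape",
    "COCO_THRESHOLDS",
]

log = logging.getLogger(__name__)

COCO_THRESHOLDS: tuple[float, ...] = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))
RECALL_ANCHORS = np.linspace(0.0, 1.0, 101)


@dataclass
class MatchResult:
    """Outcome of matching detections to ground truth at one IoU threshold."""

    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class MetricsReport:
    """Aggregate evaluation of one pipeline run."""

    precision: float
    recall: float
    ap_by_threshold: dict[float, float]
    map_coco: float
    per_tray_counts: list[tuple[str, int, int]]
    mape_percent: float
    n_trays: int
    zero_truth_false_positives: int = 0

    @property
    def counting_accuracy_percent(self) -> float:
        return 100.0 - self.mape_percent

    def to_dict(self) -> dict:
        return dict(
            precision=self.precision,
            recall=self.recall,
            ap_by_threshold={f"{t:.2f}": v for t, v in self.ap_by_threshold.items()},
            map_coco=self.map_coco,
            mape_percent=self.mape_percent,
            counting_accuracy_percent=self.counting_accuracy_percent,
            n_trays=self.n_trays,
            zero_truth_false_positives=self.zero_truth_false_positives,
        )

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_tray_counts, columns=["tray_id", "predicted_count", "manual_count"]
        )


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two half-open boxes, in [0, 1]."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _det_boxes(dets) -> list[BBox]:
    return list(dets.boxes) if isinstance(dets, DetectionSet) else list(dets)


def _greedy_flags(
    det_boxes: Sequence[BBox], gts: Sequence[BBox], iou_thresh: float
) -> tuple[list[bool], list[tuple[int, int, float]]]:
    """Greedy score-order matching; returns per-detection TP flags and pairs.

    Each detection (already in score order) takes the unmatched ground-truth
    box of highest IoU, provided that IoU strictly exceeds the threshold;
    IoU ties break toward the lower ground-truth index.
    """
    taken = [False] * len(gts)
    flags: list[bool] = []
    pairs: list[tuple[int, int, float]] = []
    for di, d in enumerate(det_boxes):
        best_j, best_iou = -1, -1.0
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            v = iou(d, g)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou > iou_thresh:
            taken[best_j] = True
            flags.append(True)
            pairs.append((di, best_j, best_iou))
        else:
            flags.append(False)
    return flags, pairs


def match_detections(dets, gts: Sequence[BBox], iou_thresh: float) -> MatchResult:
    """Match score-sorted detections to ground truth at one IoU threshold."""
    det_boxes = _det_boxes(dets)
    flags, pairs = _greedy_flags(det_boxes, gts, iou_thresh)
    tp = sum(flags)
    return MatchResult(tp=tp, fp=len(det_boxes) - tp, fn=len(gts) - tp,
                       matched_pairs=pairs)


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); zero denominators report 0."""
    if m.tp + m.fp == 0:
        log.warning("precision undefined (no detections); reporting 0")
        p = 0.0
    else:
        p = m.tp / (m.tp + m.fp)
    if m.tp + m.fn == 0:
        log.warning("recall undefined (no ground truth); reporting 0")
        r = 0.0
    else:
        r = m.tp / (m.tp + m.fn)
    return p, r


def _ap_from_flags(flags: Sequence[bool], n_gt: int) -> float:
    """101-point interpolated AP from per-detection TP flags in score order."""
    if n_gt == 0:
        log.warning("AP undefined (no ground truth); reporting 0")
        return 0.0
    if not flags:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~np.asarray(flags, dtype=bool))
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope: max precision at any recall >= r
    ap = 0.0
    for r in RECALL_ANCHORS:
        mask = recall >= r
        ap += float(precision[mask].max()) if mask.any() else 0.0
    return ap / len(RECALL_ANCHORS)


def average_precision(dets, gts: Sequence[BBox], iou_thresh: float) -> float:
    """AP at one IoU threshold (101-point interpolation, COCO convention)."""
    det_boxes = _det_boxes(dets)
    flags, _ = _greedy_flags(det_boxes, gts, iou_thresh)
    return _ap_from_flags(flags, len(gts))


def map_coco(dets, gts: Sequence[BBox]) -> float:
    """Mean AP over the ten IoU thresholds 0.50, 0.55, ..., 0.95."""
    return float(np.mean([average_precision(dets, gts, t) for t in COCO_THRESHOLDS]))


def dataset_average_precision(
    dets_by_image: Mapping[str, object],
    gts_by_image: Mapping[str, Sequence[BBox]],
    iou_thresh: float,
) -> float:
    """AP pooled over a dataset: per-image matching, global score sweep."""
    scored: list[tuple[float, bool]] = []
    n_gt = 0
    for image_id, gts in gts_by_image.items():
        n_gt += len(gts)
        det_boxes = _det_boxes(dets_by_image.get(image_id, []))
        flags, _ = _greedy_flags(det_boxes, gts, iou_thresh)
        scored.extend((b.score, f) for b, f in zip(det_boxes, flags))
    scored.sort(key=lambda t: -t[0])
    return _ap_from_flags([f for _, f in scored], n_gt)


def dataset_map_coco(dets_by_image, gts_by_image) -> dict[float, float]:
    """Per-threshold pooled AP for the ten COCO thresholds."""
    return {t: dataset_average_precision(dets_by_image, gts_by_image, t)
            for t in COCO_THRESHOLDS}


def count_plants(dets: DetectionSet, label: str = "plant") -> int:
    """Number of (already filtered) detections carrying the plant label."""
    return sum(1 for b in dets.boxes if b.label == label)


def mape(per_tray: Iterable[tuple[int, int]]) -> float:
    """Mean absolute percentage error over trays with a nonzero manual count.

    ``per_tray`` yields (predicted, manual) pairs.  Trays with manual count 0
    are excluded (the percentage error is undefined there); if every tray is
    zero-truth the metric is undefined and an error is raised.
    """
    errs = [abs(pred - man) / man for pred, man in per_tray if man > 0]
    if not errs:
        raise UndefinedMetricError("MAPE undefined: no tray has a nonzero manual count")
    return 100.0 * float(np.mean(errs))


def zero_truth_false_positives(per_tray: Iterable[tuple[int, int]]) -> int:
    """Total predicted count on trays whose manual count is zero."""
    return sum(pred for pred, man in per_tray if man == 0)
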