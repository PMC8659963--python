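"""End-to-end orchestration of the five-step counting pipeline.

Per tray: split -> frame removal -> soil segmentation -> SOR -> rasterize ->
detect -> post-filter -> count.  Each stage's point/box count is logged, and
a failure in one tray is isolated into an error record so the remaining
trays still complete.  All randomness is seeded from the configuration, so
re-running with identical inputs is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import evalmetrics
from .config import PipelineConfig
from .detect import (DetectionSet, baseline_detect, detections_to_frame,
                     filter_detections, load_external_detections)
from .exceptions import AlignmentError
from .io_cloud import AnnotationSet, PointCloud, read_cloud
from .raster import RasterImage, rasterize, sor_filter, write_png
from .soil_seg import extract_plants
from .synthetic import SceneTruth, truth_to_annotations
from .tray_split import remove_frame, split_trays

__all__ = ["TrayRecord", "PipelineResult", "run_pipeline", "evaluate"]

log = logging.getLogger(__name__)


@dataclass
class TrayRecord:
    """Outcome for a single tray."""

    tray_id: str
    image: Optional[RasterImage] = None
    detections: Optional[DetectionSet] = None
    plant_count: int = 0
    error: Optional[str] = None
    image_path: Optional[str] = None


@dataclass
class PipelineResult:
    """Per-tray outcomes of one pipeline run."""

    trays: list[TrayRecord] = field(default_factory=list)
    source_id: str = ""

    @property
    def counts(self) -> list[int]:
        return [t.plant_count for t in self.trays]


def _auto_pixel_size(cloud: PointCloud, sample: int = 2000) -> float:
    """Pixel pitch from the in-plane nearest-neighbor spacing of the cloud.

    Estimated on the frame-cleaned tray (dominated by the soil surface, a
    single layer sampled at the scan pitch); 1.25x the median spacing keeps
    one surface sample per pixel with a margin for sampling jitter.  The
    plant cloud itself would underestimate the pitch, because stacked leaf
    layers overlap in the x-y projection.
    """
    xy = cloud.xyz[:, :2]
    if len(xy) > sample:
        step = len(xy) // sample
        xy_q = xy[::step]
    else:
        xy_q = xy
    tree = cKDTree(xy)
    d, _ = tree.query(xy_q, k=2)
    med = float(np.median(d[:, 1]))
    return 1.25 * med if med > 0 else 1.0


def run_pipeline(
    raw_cloud: Union[str, Path, PointCloud],
    config: PipelineConfig = PipelineConfig(),
    out_dir: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """Run the full counting pipeline on one raw multi-tray scan."""
    if not isinstance(raw_cloud, PointCloud):
        raw_cloud = read_cloud(raw_cloud)
    log.info("input cloud %s: %d points", raw_cloud.source_id, len(raw_cloud))
    trays = split_trays(raw_cloud, config.trays)
    out = PipelineResult(source_id=raw_cloud.source_id)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.dump(out_dir / "effective_config.yaml")
    for i, tray in enumerate(trays):
        rec = TrayRecord(tray_id=tray.source_id)
        try:
            rec = _process_tray(tray, i, config, out_dir)
        except Exception as exc:  # per-tray isolation
            log.exception("tray %s failed", tray.source_id)
            rec.error = f"{type(exc).__name__}: {exc}"
        out.trays.append(rec)
    if out_dir is not None:
        detections_to_frame([t.detections for t in out.trays if t.detections]).to_csv(
            out_dir / "detections.csv", index=False)
        pd.DataFrame(
            [(t.tray_id, t.plant_count, t.error or "") for t in out.trays],
            columns=["tray_id", "predicted_count", "error"],
        ).to_csv(out_dir / "counts.csv", index=False)
    return out


def _process_tray(tray, index: int, config: PipelineConfig, out_dir) -> TrayRecord:
    rec = TrayRecord(tray_id=tray.source_id)
    cleaned = remove_frame(tray, config.trays)
    log.info("tray %s: %d -> %d points after frame removal",
             tray.source_id, len(tray), len(cleaned))
    soil_cfg = config.soil
    plants = extract_plants(
        cleaned,
        method=soil_cfg.method,
        rgs_params=soil_cfg.rgs_params(),
        ransac_threshold_mm=soil_cfg.ransac_threshold_mm,
        ransac_iterations=soil_cfg.ransac_iterations,
        rng_seed=soil_cfg.seed,
    )
    log.info("tray %s: %d plant points after soil segmentation",
             tray.source_id, len(plants))
    denoised = sor_filter(plants, config.raster.sor_params())
    log.info("tray %s: %d points after SOR", tray.source_id, len(denoised))
    px = config.raster.pixel_size_mm
    if px == "auto":
        px = _auto_pixel_size(cleaned) if len(cleaned) > 2 else 1.0
    image = rasterize(denoised, pixel_size_mm=float(px), extent=tray.tray_rect_xy,
                      image_id=tray.source_id)
    rec.image = image
    det_cfg = config.detector
    if det_cfg.backend == "baseline":
        raw_dets = baseline_detect(image, min_area_px=det_cfg.min_area_px,
                                   area_ref_px=det_cfg.area_ref_px)
    else:
        raw_dets = load_external_detections(det_cfg.external_path, tray.source_id,
                                            image_size=(image.width, image.height))
    dets = filter_detections(raw_dets, det_cfg.detector_config())
    log.info("tray %s: %d raw -> %d filtered detections",
             tray.source_id, len(raw_dets), len(dets))
    rec.detections = dets
    rec.plant_count = evalmetrics.count_plants(dets)
    if out_dir is not None:
        png = Path(out_dir) / f"{tray.source_id}.png"
        write_png(image, png)
        rec.image_path = str(png)
    return rec


def evaluate(
    result: PipelineResult,
    truth: Union[SceneTruth, Sequence[AnnotationSet]],
    manual_counts: Optional[Sequence[int]] = None,
    iou_threshold: float = 0.5,
    out_dir: Optional[Union[str, Path]] = None,
) -> evalmetrics.MetricsReport:
    """Score a pipeline run against ground truth.

    ``truth`` is either a :class:`SceneTruth` from the synthetic generator
    (annotations are derived with the run's own raster geometry, manual
    counts from the construction) or a per-tray sequence of
    :class:`AnnotationSet`, in which case ``manual_counts`` defaults to the
    per-tray annotation box counts.  Precision/recall are reported at
    ``iou_threshold``; AP is pooled over all trays at each COCO threshold.
    """
    ok_trays = [t for t in result.trays if t.error is None and t.detections is not None]
    if isinstance(truth, SceneTruth):
        if len(truth.per_tray_counts) != len(result.trays):
            raise AlignmentError(
                f"truth has {len(truth.per_tray_counts)} trays, result has {len(result.trays)}")
        images = [t.image for t in result.trays]
        if any(im is None for im in images):
            raise AlignmentError("cannot derive annotations: some trays have no image")
        annotations = truth_to_annotations(truth, images)
        manual_counts = list(truth.per_tray_counts)
    else:
        annotations = list(truth)
        ann_ids = [a.image_id for a in annotations]
        res_ids = [t.tray_id for t in result.trays]
        if len(annotations) != len(result.trays) or set(ann_ids) - set(res_ids):
            raise AlignmentError(
                f"unmatched annotation ids: {sorted(set(ann_ids) - set(res_ids))}")
        order = {a.image_id: a for a in annotations}
        annotations = [order[tid] for tid in res_ids]
        if manual_counts is None:
            manual_counts = [len(a) for a in annotations]

    dets_by_image = {t.tray_id: t.detections for t in ok_trays}
    gts_by_image = {a.image_id: a.boxes
                    for a, t in zip(annotations, result.trays) if t.error is None}
    tp = fp = fn = 0
    for t, ann in zip(result.trays, annotations):
        if t.error is not None or t.detections is None:
            continue
        m = evalmetrics.match_detections(t.detections, ann.boxes, iou_threshold)
        tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
    agg = evalmetrics.MatchResult(tp=tp, fp=fp, fn=fn)
    precision, recall = evalmetrics.precision_recall(agg)
    ap_by_threshold = evalmetrics.dataset_map_coco(dets_by_image, gts_by_image)
    map_value = float(np.mean(list(ap_by_threshold.values())))
    per_tray = [(t.tray_id, t.plant_count, int(c))
                for t, c in zip(result.trays, manual_counts)]
    pairs = [(pred, man) for _, pred, man in per_tray]
    mape_value = evalmetrics.mape(pairs)
    report = evalmetrics.MetricsReport(
        precision=precision,
        recall=recall,
        ap_by_threshold=ap_by_threshold,
        map_coco=map_value,
        per_tray_counts=per_tray,
        mape_percent=mape_value,
        n_trays=len(result.trays),
        zero_truth_false_positives=evalmetrics.zero_truth_false_positives(pairs),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        report.counts_frame().to_csv(out_dir / "per_tray_counts.csv", index=False)
    return report
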