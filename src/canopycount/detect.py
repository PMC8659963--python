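"""Plant detection on rasterized tray images (pipeline step 4).

The detection stage is deliberately pluggable.  The production-quality
detectors of the original workflow are fine-tuned CNN object detectors; this
module carries (a) the configuration schema with the post-processing values
such detectors are run with (score threshold 0.5, overlap-suppression IoU
threshold 0.2, at most 10 detections per class), (b) an adapter that ingests
detections exported by any external detector, and (c) a classical
connected-component baseline detector that operates directly on the
rasterized images, exploiting the reserved background color.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .exceptions import AnnotationValidationError, CloudParseError, ConfigError

if TYPE_CHECKING:  # pragma: no cover
    from .raster import RasterImage

__all__ = [
    "BBox",
    "DetectorConfig",
    "DetectionSet",
    "baseline_detect",
    "filter_detections",
    "load_external_detections",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box in half-open pixel coordinates [x_min, x_max) x [y_min, y_max).

    ``score`` is the detector confidence in [0, 1]; ground-truth boxes carry
    ``score=None``.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str = "plant"
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )
        if not self.label:
            raise ValueError("box label must be non-empty")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass(frozen=True)
class DetectorConfig:
    """Post-processing configuration applied to raw detections.

    Defaults follow the detector configuration the pipeline was designed
    around: overlapping boxes are suppressed above IoU 0.2, proposals below
    score 0.5 are discarded, and at most 10 detections per class are kept
    (trays hold a small, bounded number of plants).  ``aspect_ratios``
    parameterize region-proposal anchors of CNN detectors; they are validated
    and stored but have no effect on the baseline detector.
    """

    aspect_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    iou_threshold: float = 0.2
    score_threshold: float = 0.5
    max_detections_per_class: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.iou_threshold <= 1.0):
            raise ConfigError(f"iou_threshold {self.iou_threshold} outside [0, 1]")
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ConfigError(f"score_threshold {self.score_threshold} outside [0, 1]")
        if self.max_detections_per_class < 1:
            raise ConfigError("max_detections_per_class must be >= 1")
        if any(a <= 0 for a in self.aspect_ratios):
            raise ConfigError("aspect ratios must be positive")


@dataclass
class DetectionSet:
    """Scored boxes for one image, kept sorted by descending score (stable)."""

    image_id: str
    boxes: list[BBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        for b in self.boxes:
            if b.score is None:
                raise ValueError("detections require a score")
        self.boxes = sorted(self.boxes, key=lambda b: -b.score)

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self):
        return iter(self.boxes)


def baseline_detect(
    image: "RasterImage",
    min_area_px: int = 25,
    area_ref_px: float = 50.0,
    label: str = "plant",
) -> DetectionSet:
    """Detect plant blobs as 8-connected components of non-background pixels.

    Each component of area >= ``min_area_px`` yields one box tightly bounding
    it, scored ``min(1, area / area_ref_px)`` so that full-grown plants
    saturate at 1 while marginal specks score low and fall to the score
    threshold downstream.
    """
    mask = np.any(image.pixels != np.asarray(image.background_rgb, dtype=np.uint8), axis=-1)
    labeled = measure.label(mask, connectivity=2)
    boxes: list[BBox] = []
    for region in measure.regionprops(labeled):
        if region.area < min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        score = min(1.0, region.area / float(area_ref_px))
        boxes.append(
            BBox(x_min=float(c0), y_min=float(r0), x_max=float(c1), y_max=float(r1),
                 label=label, score=score)
        )
    return DetectionSet(image_id=image_id_of(image), boxes=boxes)


def image_id_of(image: "RasterImage") -> str:
    return getattr(image, "image_id", "") or ""


def filter_detections(dets: DetectionSet, cfg: DetectorConfig) -> DetectionSet:
    """Apply score thresholding, greedy overlap suppression, and truncation.

    Boxes are visited in descending score order; a box is accepted only if its
    IoU with every previously accepted box is <= ``cfg.iou_threshold``.  The
    surviving list is truncated to ``cfg.max_detections_per_class``.
    Idempotent by construction.
    """
    from .evalmetrics import iou  # local import: evalmetrics imports BBox from here

    accepted: list[BBox] = []
    for box in dets.boxes:
        if box.score < cfg.score_threshold:
            continue
        if any(iou(box, kept) > cfg.iou_threshold for kept in accepted):
            continue
        accepted.append(box)
        if len(accepted) == cfg.max_detections_per_class:
            break
    return DetectionSet(image_id=dets.image_id, boxes=accepted)


#: column order of the shared detections/annotations CSV dialect
CSV_COLUMNS = ["image_id", "label", "x_min", "y_min", "x_max", "y_max", "score"]


def load_external_detections(
    path,
    image_id: str,
    image_size: Optional[tuple[int, int]] = None,
) -> DetectionSet:
    """Read detections for ``image_id`` from a CSV in the shared dialect.

    The CSV must carry a ``score`` column (this is what distinguishes a
    detections file from a ground-truth annotations file).  Rows are returned
    sorted by descending score regardless of file order.  When ``image_size``
    (width, height) is given, boxes outside the image raise a validation
    error.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CloudParseError(f"{path}: missing required columns {missing}")
    if len(df) and df["score"].isna().any():
        raise CloudParseError(f"{path}: score column contains missing values")
    sub = df[df["image_id"].astype(str) == str(image_id)]
    boxes = [
        BBox(
            x_min=float(r.x_min), y_min=float(r.y_min),
            x_max=float(r.x_max), y_max=float(r.y_max),
            label=str(r.label), score=float(r.score),
        )
        for r in sub.itertuples()
    ]
    if image_size is not None:
        w, h = image_size
        for b in boxes:
            if b.x_min < 0 or b.y_min < 0 or b.x_max > w or b.y_max > h:
                raise AnnotationValidationError(
                    f"box ({b.x_min}, {b.y_min}, {b.x_max}, {b.y_max}) outside "
                    f"image {w}x{h} for image_id={image_id!r}"
                )
    return DetectionSet(image_id=image_id, boxes=boxes)


def detections_to_frame(sets: Sequence[DetectionSet]) -> pd.DataFrame:
    """Flatten detection sets into the shared CSV dialect."""
    rows = []
    for ds in sets:
        for b in ds.boxes:
            rows.append(
                dict(image_id=ds.image_id, label=b.label,
                     x_min=b.x_min, y_min=b.y_min, x_max=b.x_max, y_max=b.y_max,
                     score=b.score)
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)
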