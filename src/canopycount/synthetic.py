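"""Synthetic multi-tray scan generator with exact ground truth.

Scenes emulate the geometry of an outdoor tray-phenotyping scan row: PVC
trays lined up along the y axis, each holding bowl-shaped soil (less soil in
the middle of the tray than at the sides, plus level noise), a raised tray
frame, 0-8 plants modeled as a vertical stem carrying several elliptical
leaf disks, and a sparse fraction of clutter points standing in for scan
noise and barcode returns.  Every generated point is tagged by category in
the returned :class:`SceneTruth`, so each pipeline stage can be scored
against construction.

All randomness flows from a single generator seeded once; per tray the draws
happen in the fixed order soil -> frame -> plants -> clutter, so scenes are
byte-identical for identical spec + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detect import BBox
from .exceptions import GenerationError
from .io_cloud import AnnotationSet, PointCloud
from .raster import RasterImage
from .tray_split import TrayLayout

__all__ = ["SceneSpec", "PlantTruth", "SceneTruth", "generate_scene", "truth_to_annotations"]

#: minimal center separation between plants, in units of the maximal plant radius.
#: Must be >= 2 so plant footprints cannot overlap.
_SEPARATION_FACTOR = 2.4
_MAX_PLACEMENT_TRIES = 200


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scan row.

    Defaults model the mung-bean configuration: 12 trays of 64 x 40 cm per
    scan row, 0-8 plants per tray, soil sitting ~380 mm up the 425 mm tray
    with a 15 mm bowl (middle lower than the sides) and 1 mm level noise.
    ``point_spacing_mm`` sets the sampling density of soil and leaf surfaces;
    the default 4 mm keeps a full 12-tray row at desk scale while leaving
    every leaf tens of samples wide.
    """

    layout: TrayLayout = field(default_factory=TrayLayout)
    plants_per_tray: tuple[int, int] = (0, 8)
    soil_base_z_mm: float = 380.0
    soil_bowl_depth_mm: float = 15.0
    soil_noise_sd_mm: float = 1.0
    plant_height_range_mm: tuple[float, float] = (40.0, 200.0)
    leaf_count_range: tuple[int, int] = (3, 6)
    leaf_radius_range_mm: tuple[float, float] = (15.0, 35.0)
    clutter_fraction: float = 0.02
    point_spacing_mm: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("plants_per_tray", "plant_height_range_mm",
                     "leaf_count_range", "leaf_radius_range_mm"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is not ordered: ({lo}, {hi})")
        if not (0.0 <= self.clutter_fraction < 1.0):
            raise ValueError("clutter_fraction must be in [0, 1)")
        if self.point_spacing_mm <= 0:
            raise ValueError("point_spacing_mm must be positive")


@dataclass
class PlantTruth:
    """One planted individual: tray index, stem center, footprint box (mm)."""

    tray: int
    center_xy: tuple[float, float]
    box_mm: tuple[float, float, float, float]  # x0, y0, x1, y1
    point_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))


@dataclass
class SceneTruth:
    """Ground truth of a generated scene."""

    per_tray_counts: list[int]
    plants: list[PlantTruth]
    soil_indices: np.ndarray
    plant_indices: np.ndarray
    clutter_indices: np.ndarray
    rim_indices: np.ndarray
    tray_rects: list[tuple[tuple[float, float], tuple[float, float]]]

    def plants_in_tray(self, tray: int) -> list[PlantTruth]:
        return [p for p in self.plants if p.tray == tray]


def _jittered_grid(rng, x0, x1, y0, y1, spacing) -> np.ndarray:
    """Grid points over [x0,x1] x [y0,y1] with +-0.4 spacing jitter."""
    xs = np.arange(x0 + spacing / 2, x1, spacing)
    ys = np.arange(y0 + spacing / 2, y1, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts += rng.uniform(-0.4 * spacing, 0.4 * spacing, size=pts.shape)
    return pts


def _soil_z(spec: SceneSpec, xy: np.ndarray, inner: tuple[float, float, float, float]) -> np.ndarray:
    """Bowl-shaped soil level: lowest at the tray center, base level at the sides.

    A separable cosine bowl: depth tapers smoothly to zero at the inner tray
    walls, with a broad low region in the middle, the way watered soil settles.
    """
    x0, x1, y0, y1 = inner
    u = 2.0 * (xy[:, 0] - x0) / (x1 - x0) - 1.0
    v = 2.0 * (xy[:, 1] - y0) / (y1 - y0) - 1.0
    bowl = (np.cos(np.clip(u, -1, 1) * np.pi / 2)
            * np.cos(np.clip(v, -1, 1) * np.pi / 2))
    return spec.soil_base_z_mm - spec.soil_bowl_depth_mm * bowl


def _sample_plant(rng, spec: SceneSpec, cx: float, cy: float, soil_z: float
                  ) -> tuple[np.ndarray, tuple[float, float, float, float]]:
    """Points of one plant: vertical stem + elliptical leaf disks.

    The plant's footprint radius R is drawn from ``leaf_radius_range_mm``;
    each leaf disk (radius <= R minus its offset from the stem) stays inside
    that footprint, so plants separated by >= 2R cannot overlap.
    """
    s = spec.point_spacing_mm
    height = rng.uniform(*spec.plant_height_range_mm)
    R = rng.uniform(*spec.leaf_radius_range_mm)
    n_leaves = int(rng.integers(spec.leaf_count_range[0], spec.leaf_count_range[1] + 1))

    pts = []
    stem_z = np.arange(0.0, height, s / 2)
    stem = np.column_stack([
        np.full_like(stem_z, cx), np.full_like(stem_z, cy), soil_z + stem_z
    ])
    stem[:, :2] += rng.normal(0.0, 0.3, size=(len(stem), 2))
    pts.append(stem)
    for _ in range(n_leaves):
        r_leaf = R * rng.uniform(0.5, 1.0)
        max_off = R - r_leaf
        ang = rng.uniform(0.0, 2 * math.pi)
        off = rng.uniform(0.0, max_off)
        lx, ly = cx + off * math.cos(ang), cy + off * math.sin(ang)
        h_leaf = height * rng.uniform(0.3, 1.0)
        # jittered grid clipped to a rotated ellipse
        grid = _jittered_grid(rng, lx - r_leaf, lx + r_leaf, ly - r_leaf, ly + r_leaf, s)
        ratio = rng.uniform(0.6, 1.0)
        theta = rng.uniform(0.0, math.pi)
        dx, dy = grid[:, 0] - lx, grid[:, 1] - ly
        ex = dx * math.cos(theta) + dy * math.sin(theta)
        ey = -dx * math.sin(theta) + dy * math.cos(theta)
        inside = (ex / r_leaf) ** 2 + (ey / (r_leaf * ratio)) ** 2 <= 1.0
        leaf = grid[inside]
        z = soil_z + h_leaf + rng.normal(0.0, 0.5, size=len(leaf))
        pts.append(np.column_stack([leaf, z]))
    all_pts = np.vstack(pts)
    box = (float(all_pts[:, 0].min()), float(all_pts[:, 1].min()),
           float(all_pts[:, 0].max()), float(all_pts[:, 1].max()))
    return all_pts, box


def generate_scene(spec: SceneSpec) -> tuple[PointCloud, SceneTruth]:
    """Generate one scan row and its exact ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    lay = spec.layout
    fw = lay.frame_width_mm
    r_max = spec.leaf_radius_range_mm[1]
    min_sep = _SEPARATION_FACTOR * r_max

    chunks: list[np.ndarray] = []
    cats: list[np.ndarray] = []  # 0 soil, 1 rim, 2 plant, 3 clutter
    plants: list[PlantTruth] = []
    per_tray_counts: list[int] = []
    tray_rects = []
    offset = 0  # running global point index

    def push(arr: np.ndarray, cat: int) -> np.ndarray:
        """Append a chunk; return the global indices it occupies."""
        nonlocal offset
        chunks.append(arr)
        cats.append(np.full(len(arr), cat, dtype=np.int8))
        idx = np.arange(offset, offset + len(arr))
        offset += len(arr)
        return idx

    for t in range(lay.n_trays):
        x0, x1 = 0.0, lay.tray_length_mm
        y0, y1 = t * lay.tray_width_mm, (t + 1) * lay.tray_width_mm
        tray_rects.append(((x0, x1), (y0, y1)))
        inner = (x0 + fw, x1 - fw, y0 + fw, y1 - fw)

        # 1. soil
        soil_xy = _jittered_grid(rng, inner[0], inner[1], inner[2], inner[3],
                                 spec.point_spacing_mm)
        soil_z = _soil_z(spec, soil_xy, inner) + rng.normal(
            0.0, spec.soil_noise_sd_mm, size=len(soil_xy))
        push(np.column_stack([soil_xy, soil_z]), 0)

        # 2. tray frame: band of width fw along the tray border, at rim height
        grid = _jittered_grid(rng, x0, x1, y0, y1, spec.point_spacing_mm)
        margin = np.minimum.reduce([
            grid[:, 0] - x0, x1 - grid[:, 0], grid[:, 1] - y0, y1 - grid[:, 1]])
        rim_xy = grid[margin < fw * 0.75]
        rim_z = np.full(len(rim_xy), lay.tray_height_mm) + rng.normal(
            0.0, 0.5, size=len(rim_xy))
        push(np.column_stack([rim_xy, rim_z]), 1)

        # 3. plants, rejection-sampled non-overlapping centers
        n_plants = int(rng.integers(spec.plants_per_tray[0], spec.plants_per_tray[1] + 1))
        centers: list[tuple[float, float]] = []
        px0, px1 = inner[0] + r_max, inner[1] - r_max
        py0, py1 = inner[2] + r_max, inner[3] - r_max
        if n_plants > 0 and (px1 <= px0 or py1 <= py0):
            raise GenerationError("tray too small for the requested leaf radius")
        for _ in range(n_plants):
            for _try in range(_MAX_PLACEMENT_TRIES):
                cx = rng.uniform(px0, px1)
                cy = rng.uniform(py0, py1)
                if all((cx - ox) ** 2 + (cy - oy) ** 2 >= min_sep ** 2
                       for ox, oy in centers):
                    centers.append((cx, cy))
                    break
            else:
                raise GenerationError(
                    f"could not place {n_plants} non-overlapping plants in tray {t}; "
                    "reduce plants_per_tray or leaf radius")
        n_plant_pts = 0
        for cx, cy in centers:
            local_soil = float(_soil_z(spec, np.array([[cx, cy]]), inner)[0])
            pts, box = _sample_plant(rng, spec, cx, cy, local_soil)
            idx = push(pts, 2)
            n_plant_pts += len(pts)
            plants.append(PlantTruth(tray=t, center_xy=(cx, cy), box_mm=box,
                                     point_indices=idx))
        per_tray_counts.append(n_plants)

        # 4. clutter, proportional to the tray's structured points
        n_struct = len(soil_xy) + len(rim_xy) + n_plant_pts
        n_clutter = int(round(spec.clutter_fraction * n_struct))
        if n_clutter > 0:
            cx_ = rng.uniform(x0, x1, n_clutter)
            cy_ = rng.uniform(y0, y1, n_clutter)
            cz_ = rng.uniform(0.0, lay.tray_height_mm, n_clutter)
            push(np.column_stack([cx_, cy_, cz_]), 3)

    xyz = np.vstack(chunks) if chunks else np.empty((0, 3))
    cat = np.concatenate(cats) if cats else np.empty(0, dtype=np.int8)
    truth = SceneTruth(
        per_tray_counts=per_tray_counts,
        plants=plants,
        soil_indices=np.flatnonzero(cat == 0),
        plant_indices=np.flatnonzero(cat == 2),
        clutter_indices=np.flatnonzero(cat == 3),
        rim_indices=np.flatnonzero(cat == 1),
        tray_rects=tray_rects,
    )
    cloud = PointCloud(xyz=xyz, source_id=f"synthetic_seed{spec.rng_seed}")
    return cloud, truth


def truth_to_annotations(
    truth: SceneTruth,
    images: Sequence[RasterImage],
) -> list[AnnotationSet]:
    """Convert world-mm plant footprints into per-tray pixel annotations.

    One :class:`RasterImage` per tray supplies the pixel size and origin.
    Boxes are converted with floor/ceil so the footprint is fully covered,
    clipped to the image bounds, and dropped with a warning if clipping
    leaves them empty.
    """
    import logging
    log = logging.getLogger(__name__)
    if len(images) != len(truth.per_tray_counts):
        raise ValueError(
            f"{len(images)} images for {len(truth.per_tray_counts)} trays")
    out = []
    for t, img in enumerate(images):
        s = img.pixel_size_mm
        ox, oy = img.origin_xy_mm
        boxes = []
        for p in truth.plants_in_tray(t):
            bx0, by0, bx1, by1 = p.box_mm
            x_min = max(0.0, math.floor((bx0 - ox) / s))
            y_min = max(0.0, math.floor((by0 - oy) / s))
            x_max = min(float(img.width), math.ceil((bx1 - ox) / s))
            y_max = min(float(img.height), math.ceil((by1 - oy) / s))
            if x_max <= x_min or y_max <= y_min:
                log.warning("dropping degenerate annotation box for tray %d", t)
                continue
            boxes.append(BBox(x_min=x_min, y_min=y_min, x_max=x_max, y_max=y_max,
                              label="plant"))
        out.append(AnnotationSet(image_id=img.image_id or f"tray{t:02d}", boxes=boxes,
                                 image_width=img.width, image_height=img.height))
    return out
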