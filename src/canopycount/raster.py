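"""Step 3 — denoise the plant cloud and rasterize it to a height-colored image.

A Statistical Outlier Removal (SOR) pass first drops points whose mean
k-nearest-neighbor distance is anomalously large.  The surviving plant
points are then projected onto the x-y plane into a pixel grid; each
occupied pixel takes the maximum z of its points (canopy-surface view, the
scanner looks from above) and is colored by a blue -> green -> red height
ramp normalized per tray: the lowest canopy points are blue, medium heights
green, the highest red.  Empty pixels take a reserved background color
(black by default) so the detector sees zero texture where no plant exists.

Pixel rows follow the mathematical orientation (row 0 = minimal y); the PNG
writer flips to the top-left-origin image convention.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy.spatial import cKDTree

from .io_cloud import PointCloud

__all__ = [
    "RasterImage",
    "SorParams",
    "sor_filter",
    "height_to_color",
    "rasterize",
    "write_png",
    "read_png",
]

log = logging.getLogger(__name__)

BACKGROUND_RGB = (0, 0, 0)


@dataclass(frozen=True)
class SorParams:
    """SOR filter: remove points with mean k-NN distance > mean + mult * std."""

    k_neighbors: int = 16
    std_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1 or self.std_multiplier <= 0:
            raise ValueError("SOR parameters must be positive")


@dataclass
class RasterImage:
    """H x W RGB grid with its pixel <-> mm mapping.

    ``origin_xy_mm`` is the world position of the lower-left corner of pixel
    (row 0, col 0).  ``background_rgb`` is reserved: no plant pixel ever
    equals it exactly.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    origin_xy_mm: tuple[float, float]
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an HxWx3 array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def sor_filter(cloud: PointCloud, params: SorParams = SorParams()) -> PointCloud:
    """Statistical outlier removal, order-preserving.

    For each point the mean distance to its ``k_neighbors`` nearest neighbors
    is computed; points whose mean distance exceeds the global mean by more
    than ``std_multiplier`` standard deviations are removed.  Clouds with too
    few points are returned unchanged with a warning.
    """
    n = len(cloud)
    if n <= params.k_neighbors:
        log.warning("SOR skipped: %d points <= k=%d", n, params.k_neighbors)
        return cloud
    tree = cKDTree(cloud.xyz)
    dist, _ = tree.query(cloud.xyz, k=params.k_neighbors + 1)
    mean_d = dist[:, 1:].mean(axis=1)
    thr = mean_d.mean() + params.std_multiplier * mean_d.std()
    return cloud.subset(mean_d <= thr)


def height_to_color(h_norm: float) -> tuple[int, int, int]:
    """Map normalized height in [0, 1] to the blue -> green -> red ramp.

    0 -> (0, 0, 255); 0.5 -> (0, 255, 0); 1 -> (255, 0, 0), linear within
    each half.  Out-of-range inputs are clamped with a warning.
    """
    if not (0.0 <= h_norm <= 1.0):
        log.warning("height %g outside [0, 1]; clamping", h_norm)
        h_norm = min(1.0, max(0.0, h_norm))
    r, g, b = _colormap(np.asarray([h_norm]))[0]
    return int(r), int(g), int(b)


def _colormap(h: np.ndarray) -> np.ndarray:
    """Vectorized blue->green->red ramp; returns uint8 (N, 3)."""
    h = np.clip(h, 0.0, 1.0)
    rgb = np.zeros((len(h), 3))
    lo = h <= 0.5
    rgb[lo, 1] = 2.0 * h[lo] * 255.0
    rgb[lo, 2] = (1.0 - 2.0 * h[lo]) * 255.0
    hi = ~lo
    rgb[hi, 0] = (2.0 * h[hi] - 1.0) * 255.0
    rgb[hi, 1] = (2.0 - 2.0 * h[hi]) * 255.0
    return np.rint(rgb).astype(np.uint8)


def rasterize(
    cloud: PointCloud,
    pixel_size_mm: float = 0.8,
    extent: Optional[tuple[tuple[float, float], tuple[float, float]]] = None,
    image_id: str = "",
) -> RasterImage:
    """Project plant points onto the x-y grid, colored by normalized height.

    Pixel (col, row) = (floor((x - x0)/s), floor((y - y0)/s)); per pixel the
    maximum z wins; z is normalized to [0, 1] over the cloud's own z range
    (per-tray normalization).  A degenerate z range maps everything to blue.
    Points outside the extent are ignored; points exactly on the upper edge
    fall into the last cell.
    """
    if pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be positive")
    if extent is None:
        extent = cloud.tray_rect_xy
    if extent is None:
        if len(cloud) == 0:
            raise ValueError("cannot infer extent from an empty cloud")
        extent = (
            (float(cloud.xyz[:, 0].min()), float(cloud.xyz[:, 0].max())),
            (float(cloud.xyz[:, 1].min()), float(cloud.xyz[:, 1].max())),
        )
    (x0, x1), (y0, y1) = extent
    s = pixel_size_mm
    width = max(1, math.ceil((x1 - x0) / s))
    height = max(1, math.ceil((y1 - y0) / s))
    pixels = np.zeros((height, width, 3), dtype=np.uint8)
    pixels[:, :] = BACKGROUND_RGB
    img = RasterImage(pixels=pixels, pixel_size_mm=s, origin_xy_mm=(x0, y0),
                      image_id=image_id)
    if len(cloud) == 0:
        return img
    x, y, z = cloud.xyz.T
    inside = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    if not inside.any():
        return img
    x, y, z = x[inside], y[inside], z[inside]
    col = np.minimum(np.floor((x - x0) / s).astype(np.intp), width - 1)
    row = np.minimum(np.floor((y - y0) / s).astype(np.intp), height - 1)
    zmax = np.full((height, width), -np.inf)
    np.maximum.at(zmax, (row, col), z)
    occupied = np.isfinite(zmax)
    z_lo, z_hi = float(z.min()), float(z.max())
    if z_hi > z_lo:
        h_norm = (zmax[occupied] - z_lo) / (z_hi - z_lo)
    else:
        h_norm = np.zeros(int(occupied.sum()))
    img.pixels[occupied] = _colormap(h_norm)
    return img


def write_png(image: RasterImage, path) -> None:
    """Export 8-bit RGB PNG (top-left origin) plus a JSON geometry sidecar."""
    path = Path(path)
    Image.fromarray(np.flipud(image.pixels)).save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(
            dict(pixel_size_mm=image.pixel_size_mm,
                 origin_xy_mm=list(image.origin_xy_mm),
                 background_rgb=list(image.background_rgb),
                 image_id=image.image_id),
            fh,
        )


def read_png(path) -> RasterImage:
    """Read a PNG written by :func:`write_png`, restoring the geometry."""
    path = Path(path)
    arr = np.flipud(np.asarray(Image.open(path).convert("RGB"))).copy()
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = dict(pixel_size_mm=1.0, origin_xy_mm=(0.0, 0.0),
                background_rgb=BACKGROUND_RGB, image_id=path.stem)
    if sidecar.exists():
        with open(sidecar) as fh:
            loaded = json.load(fh)
        meta.update(loaded)
    return RasterImage(
        pixels=arr,
        pixel_size_mm=float(meta["pixel_size_mm"]),
        origin_xy_mm=tuple(meta["origin_xy_mm"]),
        background_rgb=tuple(meta["background_rgb"]),
        image_id=str(meta["image_id"]),
    )
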