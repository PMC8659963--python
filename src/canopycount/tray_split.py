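"""Step 1 — split a multi-tray scan row into per-tray clouds and strip tray frames.

A raw scan file covers one row of trays lined up along the y axis.  The
observed y-extent of the file is divided into ``n_trays`` equal half-open
intervals (last interval closed), which is robust to varying scan origins.
The PVC frame of each tray is then removed with an x-y margin test against
the tray's native rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ConfigError
from .io_cloud import PointCloud

__all__ = ["TrayLayout", "split_trays", "remove_frame"]


@dataclass(frozen=True)
class TrayLayout:
    """Nominal geometry of one tray row.

    Defaults are the mung-bean tray: 64 x 40 x 42.5 cm, 12 trays per scan
    row.  ``frame_width_mm`` is the rim thickness stripped from each tray
    edge; it is an operator-configured value (default 20 mm).
    """

    n_trays: int = 12
    tray_length_mm: float = 640.0
    tray_width_mm: float = 400.0
    tray_height_mm: float = 425.0
    frame_width_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.n_trays < 1:
            raise ConfigError(f"n_trays must be >= 1, got {self.n_trays}")
        for name in ("tray_length_mm", "tray_width_mm", "tray_height_mm", "frame_width_mm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.frame_width_mm >= min(self.tray_length_mm, self.tray_width_mm) / 2:
            raise ConfigError("frame_width_mm must be less than half the smallest tray side")


def split_trays(cloud: PointCloud, layout: TrayLayout) -> list[PointCloud]:
    """Partition the cloud into ``layout.n_trays`` equal y-intervals.

    Interval i is [y_min + i*h, y_min + (i+1)*h) with h the extent divided by
    the tray count; the last interval is closed so the partition is complete.
    A point exactly on an interior boundary goes to the higher-index tray.
    """
    if len(cloud) == 0:
        raise ValueError("cannot split an empty cloud")
    n = layout.n_trays
    y = cloud.xyz[:, 1]
    y_min, y_max = float(y.min()), float(y.max())
    span = y_max - y_min
    if span == 0.0:
        idx = np.zeros(len(cloud), dtype=np.intp)
    else:
        idx = np.floor((y - y_min) / span * n).astype(np.intp)
        np.clip(idx, 0, n - 1, out=idx)
    x_min, x_max = float(cloud.xyz[:, 0].min()), float(cloud.xyz[:, 0].max())
    h = span / n if span > 0 else 0.0
    trays = []
    for i in range(n):
        tray = cloud.subset(idx == i)
        tray.source_id = f"{cloud.source_id}_tray{i:02d}" if cloud.source_id else f"tray{i:02d}"
        tray.tray_rect_xy = ((x_min, x_max), (y_min + i * h, y_min + (i + 1) * h))
        trays.append(tray)
    return trays


def remove_frame(
    tray: PointCloud,
    layout: TrayLayout,
    rect: Optional[tuple[tuple[float, float], tuple[float, float]]] = None,
) -> PointCloud:
    """Drop points within ``frame_width_mm`` of the tray rectangle boundary.

    The rectangle defaults to the tray's native rectangle recorded by
    :func:`split_trays` (falling back to the cloud's x-y bounding box), and
    is carried over to the output so the operation is idempotent.
    """
    if rect is None:
        rect = tray.tray_rect_xy
    if rect is None:
        if len(tray) == 0:
            return tray.subset(np.zeros(0, dtype=bool))
        rect = (
            (float(tray.xyz[:, 0].min()), float(tray.xyz[:, 0].max())),
            (float(tray.xyz[:, 1].min()), float(tray.xyz[:, 1].max())),
        )
    (x0, x1), (y0, y1) = rect
    fw = layout.frame_width_mm
    x, y = tray.xyz[:, 0], tray.xyz[:, 1]
    keep = (x - x0 >= fw) & (x1 - x >= fw) & (y - y0 >= fw) & (y1 - y >= fw)
    out = tray.subset(keep)
    out.tray_rect_xy = rect
    return out
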