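"""Point-cloud and bounding-box annotation I/O.

Clouds are exchanged as ASCII PLY (vertex properties ``x, y, z`` and
optionally ``intensity``) or as plain delimited XYZ text with 3 or 4 numeric
columns.  All coordinates are millimeters.  Laser-reflection intensity is
preserved on round trips but never used downstream: it is not a reliable
color signal.

Annotations are exchanged as Pascal-VOC XML or as a CSV dialect with header
``image_id,label,x_min,y_min,x_max,y_max,score`` (score left empty for ground
truth).  Box coordinates use the half-open pixel convention.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .detect import CSV_COLUMNS, BBox
from .exceptions import (
    AnnotationValidationError,
    CloudParseError,
    UnsupportedFormatError,
)

__all__ = [
    "PointCloud",
    "AnnotationSet",
    "read_cloud",
    "write_cloud",
    "read_annotations",
    "write_annotations",
]


@dataclass
class PointCloud:
    """N points in mm world coordinates, with optional laser intensity.

    ``tray_rect_xy`` is set by the tray splitter: it records the x-y
    rectangle the tray natively occupies so that downstream geometric
    filters (frame removal, rasterization) operate on a stable extent
    rather than on a data-dependent bounding box.
    """

    xyz: np.ndarray
    intensity: Optional[np.ndarray] = None
    source_id: str = ""
    tray_rect_xy: Optional[tuple[tuple[float, float], tuple[float, float]]] = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point coordinates must be finite")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=np.float64).ravel()
            if len(self.intensity) != len(self.xyz):
                raise ValueError(
                    f"intensity length {len(self.intensity)} != point count {len(self.xyz)}"
                )

    def __len__(self) -> int:
        return len(self.xyz)

    def subset(self, index) -> "PointCloud":
        """A new cloud holding the selected points, metadata preserved."""
        return PointCloud(
            xyz=self.xyz[index],
            intensity=None if self.intensity is None else self.intensity[index],
            source_id=self.source_id,
            tray_rect_xy=self.tray_rect_xy,
        )


@dataclass
class AnnotationSet:
    """Ground-truth boxes for one image."""

    image_id: str
    boxes: list[BBox] = field(default_factory=list)
    image_width: int = 0
    image_height: int = 0

    def __post_init__(self) -> None:
        for b in self.boxes:
            if (b.x_min < 0 or b.y_min < 0
                    or b.x_max > self.image_width or b.y_max > self.image_height):
                raise AnnotationValidationError(
                    f"box ({b.x_min}, {b.y_min}, {b.x_max}, {b.y_max}) outside "
                    f"declared image {self.image_width}x{self.image_height} "
                    f"in {self.image_id!r}"
                )

    def __len__(self) -> int:
        return len(self.boxes)


# ---------------------------------------------------------------------------
# point clouds


def _sniff_format(path: Path) -> str:
    with open(path, "rb") as fh:
        head = fh.read(4)
    return "ply" if head[:3] == b"ply" else "xyz"


def read_cloud(path, format_hint: str = "auto") -> PointCloud:
    """Read an ASCII PLY or delimited XYZ(+intensity) file.

    Binary PLY is rejected explicitly.  Malformed numeric rows raise a parse
    error naming the offending line.
    """
    path = Path(path)
    if format_hint == "auto":
        format_hint = _sniff_format(path)
    if format_hint == "ply":
        xyz, intensity = _read_ply(path)
    elif format_hint == "xyz":
        xyz, intensity = _read_xyz(path)
    else:
        raise ValueError(f"unknown format hint {format_hint!r}")
    return PointCloud(xyz=xyz, intensity=intensity, source_id=path.stem)


def _read_ply(path: Path) -> tuple[np.ndarray, Optional[np.ndarray]]:
    with open(path, "r", errors="replace") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise CloudParseError(f"{path}: line 1: not a PLY file")
    n_vertex = None
    props: list[str] = []
    in_vertex_element = False
    body_start = None
    for i, line in enumerate(lines[1:], start=2):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            if len(tok) < 2 or tok[1] != "ascii":
                raise UnsupportedFormatError(
                    f"{path}: line {i}: only ASCII PLY is supported (got {line.strip()!r})"
                )
        elif tok[0] == "element":
            in_vertex_element = tok[1] == "vertex"
            if in_vertex_element:
                try:
                    n_vertex = int(tok[2])
                except (IndexError, ValueError):
                    raise CloudParseError(f"{path}: line {i}: bad element line {line!r}")
        elif tok[0] == "property" and in_vertex_element:
            props.append(tok[-1])
        elif tok[0] == "end_header":
            body_start = i
            break
    if body_start is None or n_vertex is None:
        raise CloudParseError(f"{path}: incomplete PLY header")
    for axis in ("x", "y", "z"):
        if axis not in props:
            raise CloudParseError(f"{path}: vertex element lacks property {axis!r}")
    idx = [props.index(a) for a in ("x", "y", "z")]
    int_name = next((p for p in props if p in ("intensity", "scalar_intensity")), None)
    int_idx = props.index(int_name) if int_name else None

    rows = np.empty((n_vertex, 3))
    intensity = np.empty(n_vertex) if int_idx is not None else None
    for j in range(n_vertex):
        lineno = body_start + 1 + j
        if lineno > len(lines):
            raise CloudParseError(f"{path}: line {lineno}: expected {n_vertex} vertices, file ended")
        tok = lines[lineno - 1].split()
        if len(tok) < len(props):
            raise CloudParseError(f"{path}: line {lineno}: expected {len(props)} values, got {len(tok)}")
        try:
            rows[j] = [float(tok[k]) for k in idx]
            if intensity is not None:
                intensity[j] = float(tok[int_idx])
        except ValueError:
            raise CloudParseError(f"{path}: line {lineno}: non-numeric value in {lines[lineno - 1]!r}")
    return rows, intensity


def _read_xyz(path: Path) -> tuple[np.ndarray, Optional[np.ndarray]]:
    rows: list[list[float]] = []
    ncol = None
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.replace(",", " ").split()
            if ncol is None:
                ncol = len(tok)
                if ncol not in (3, 4):
                    raise CloudParseError(f"{path}: line {lineno}: expected 3 or 4 columns, got {ncol}")
            if len(tok) != ncol:
                raise CloudParseError(f"{path}: line {lineno}: expected {ncol} columns, got {len(tok)}")
            try:
                rows.append([float(t) for t in tok])
            except ValueError:
                raise CloudParseError(f"{path}: line {lineno}: non-numeric value in {line!r}")
    arr = np.asarray(rows, dtype=np.float64).reshape(-1, ncol or 3)
    if arr.shape[1] == 4:
        return arr[:, :3], arr[:, 3]
    return arr, None


def write_cloud(cloud: PointCloud, path, format: str = "ply") -> None:
    """Write a cloud as ASCII PLY or delimited XYZ, preserving point order."""
    path = Path(path)
    if format == "ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(cloud)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            if cloud.intensity is not None:
                fh.write("property float intensity\n")
            fh.write("end_header\n")
            for i, (x, y, z) in enumerate(cloud.xyz):
                if cloud.intensity is not None:
                    fh.write(f"{x:.6g} {y:.6g} {z:.6g} {cloud.intensity[i]:.6g}\n")
                else:
                    fh.write(f"{x:.6g} {y:.6g} {z:.6g}\n")
    elif format == "xyz":
        with open(path, "w") as fh:
            for i, (x, y, z) in enumerate(cloud.xyz):
                if cloud.intensity is not None:
                    fh.write(f"{x:.6g} {y:.6g} {z:.6g} {cloud.intensity[i]:.6g}\n")
                else:
                    fh.write(f"{x:.6g} {y:.6g} {z:.6g}\n")
    else:
        raise ValueError(f"unknown cloud format {format!r}")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path, format: str = "auto") -> AnnotationSet:
    """Read ground-truth boxes from Pascal-VOC XML or the shared CSV dialect."""
    path = Path(path)
    if format == "auto":
        format = "voc_xml" if path.suffix.lower() == ".xml" else "csv"
    if format == "voc_xml":
        return _read_voc_xml(path)
    if format == "csv":
        return _read_annotation_csv(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_voc_xml(path: Path) -> AnnotationSet:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise CloudParseError(f"{path}: invalid XML: {exc}")
    filename = root.findtext("filename", default=path.stem)
    size = root.find("size")
    width = int(size.findtext("width")) if size is not None else 0
    height = int(size.findtext("height")) if size is not None else 0
    boxes = []
    for obj in root.iter("object"):
        name = obj.findtext("name", default="plant")
        bnd = obj.find("bndbox")
        boxes.append(
            BBox(
                x_min=float(bnd.findtext("xmin")),
                y_min=float(bnd.findtext("ymin")),
                x_max=float(bnd.findtext("xmax")),
                y_max=float(bnd.findtext("ymax")),
                label=name,
            )
        )
    return AnnotationSet(image_id=Path(filename).stem, boxes=boxes,
                         image_width=width, image_height=height)


def _read_annotation_csv(path: Path) -> AnnotationSet:
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise CloudParseError(f"{path}: missing required columns {missing}")
    boxes = [
        BBox(x_min=float(r.x_min), y_min=float(r.y_min),
             x_max=float(r.x_max), y_max=float(r.y_max), label=str(r.label))
        for r in df.itertuples()
    ]
    image_id = str(df["image_id"].iloc[0]) if len(df) else Path(path).stem
    width = int(df["image_width"].iloc[0]) if "image_width" in df.columns and len(df) else _ceil_extent(boxes, "x")
    height = int(df["image_height"].iloc[0]) if "image_height" in df.columns and len(df) else _ceil_extent(boxes, "y")
    return AnnotationSet(image_id=image_id, boxes=boxes,
                         image_width=width, image_height=height)


def _ceil_extent(boxes: list[BBox], axis: str) -> int:
    if not boxes:
        return 0
    hi = max(b.x_max if axis == "x" else b.y_max for b in boxes)
    return int(np.ceil(hi))


def write_annotations(ann: AnnotationSet, path, format: str = "auto") -> None:
    path = Path(path)
    if format == "auto":
        format = "voc_xml" if path.suffix.lower() == ".xml" else "csv"
    if format == "voc_xml":
        _write_voc_xml(ann, path)
    elif format == "csv":
        rows = [
            dict(image_id=ann.image_id, label=b.label,
                 x_min=b.x_min, y_min=b.y_min, x_max=b.x_max, y_max=b.y_max,
                 score="", image_width=ann.image_width, image_height=ann.image_height)
            for b in ann.boxes
        ]
        pd.DataFrame(rows, columns=CSV_COLUMNS + ["image_width", "image_height"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown annotation format {format!r}")


def _write_voc_xml(ann: AnnotationSet, path: Path) -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = f"{ann.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.image_width)
    ET.SubElement(size, "height").text = str(ann.image_height)
    ET.SubElement(size, "depth").text = "3"
    for b in ann.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = b.label
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = f"{b.x_min:g}"
        ET.SubElement(bnd, "ymin").text = f"{b.y_min:g}"
        ET.SubElement(bnd, "xmax").text = f"{b.x_max:g}"
        ET.SubElement(bnd, "ymax").text = f"{b.y_max:g}"
    ET.ElementTree(root).write(path, encoding="unicode")
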