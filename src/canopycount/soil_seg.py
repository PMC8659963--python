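"""Step 2 — separate plant points from the soil surface.

Soil in the trays is not flat: there is less soil in the middle of a tray
than at its sides, and the soil level differs between trays, so a fixed
height cut either keeps too much soil or deletes low plants.  Two surface
models are provided instead:

* **Region Growing Segmentation (RGS)** — the preferred method.  Per-point
  surface normals and curvatures are estimated from k-nearest-neighbor
  covariances; regions grow from low-curvature seeds, admitting neighbors
  whose normals deviate from the expanding seed's normal by less than a
  smoothness angle.  The largest resulting cluster is taken to be soil.
* **RANSAC plane consensus** — repeatedly fits planes to random 3-point
  samples and keeps the hypothesis with the most inliers; soil points are
  the inliers, plants the outliers.  A least-squares refit on the consensus
  set follows.  Because real tray soil is bowl-shaped, a single plane tends
  to leave some soil behind, which is why RGS is the default.

A naive fixed-height cut (:func:`fixed_height_cut`) is included as the
rejected baseline, for comparison experiments.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import DegenerateGeometryError, ParameterError
from .io_cloud import PointCloud

__all__ = [
    "NormalsField",
    "SegmentationResult",
    "PlaneModel",
    "RgsParams",
    "estimate_normals",
    "region_growing",
    "ransac_plane",
    "extract_plants",
    "fixed_height_cut",
]

log = logging.getLogger(__name__)

UNCLUSTERED = -1


@dataclass
class NormalsField:
    """Per-point unit normals and surface-variation curvature.

    Curvature is lambda0 / (lambda0 + lambda1 + lambda2) of the local
    covariance eigenvalues (lambda0 smallest); it lies in [0, 1/3] and is 0
    on perfectly flat neighborhoods.
    """

    normals: np.ndarray
    curvature: np.ndarray
    k_neighbors: int


@dataclass
class SegmentationResult:
    """Cluster labels per point; ``soil_label`` marks the largest cluster."""

    labels: np.ndarray
    soil_label: int
    cluster_sizes: dict[int, int]


@dataclass
class PlaneModel:
    """Plane normal . p = offset (mm), with the consensus inlier set."""

    normal: np.ndarray
    offset: float
    inlier_indices: np.ndarray


@dataclass(frozen=True)
class RgsParams:
    """Region-growing parameters.

    ``angle_threshold_deg`` is the smoothness criterion; ``curvature_threshold``
    decides which admitted points re-seed the growth (the default 1.0 lets
    every admitted point act as a seed, since surface-variation curvature
    never exceeds 1/3); clusters below ``min_cluster_size`` become noise.

    ``normals_k`` decouples the normal-estimation neighborhood from the
    growth neighborhood: normals benefit from a larger support (smoother
    under sensor noise) while the growth reach should stay below the
    geometric separation between surfaces.  ``None`` means use ``k_neighbors``.
    """

    k_neighbors: int = 30
    angle_threshold_deg: float = 3.0
    curvature_threshold: float = 1.0
    min_cluster_size: int = 50
    normals_k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k_neighbors < 3:
            raise ParameterError("k_neighbors must be >= 3")
        if not (0.0 < self.angle_threshold_deg < 90.0):
            raise ParameterError("angle_threshold_deg must be in (0, 90)")
        if self.curvature_threshold <= 0 or self.min_cluster_size <= 0:
            raise ParameterError("curvature_threshold and min_cluster_size must be positive")
        if self.normals_k is not None and self.normals_k < 3:
            raise ParameterError("normals_k must be >= 3")


def _orient(normals: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Flip unit normals into the canonical half-space: z > 0, ties by +y then +x.

    Components within ``tol`` of zero are treated as zero so that exactly
    horizontal surfaces (z component lost to rounding) get a deterministic sign.
    """
    n = normals.copy()
    z, y, x = n[:, 2], n[:, 1], n[:, 0]
    z0 = np.abs(z) <= tol
    y0 = np.abs(y) <= tol
    flip = (~z0 & (z < 0)) | (z0 & ~y0 & (y < 0)) | (z0 & y0 & (x < 0))
    n[flip] *= -1.0
    return n


def estimate_normals(cloud: PointCloud, k: int = 30) -> NormalsField:
    """Estimate per-point normals and curvature from k-NN covariances.

    The normal is the eigenvector of the neighborhood covariance with the
    smallest eigenvalue, oriented into the z >= 0 half-space (sign fixed by
    +y, then +x, for exactly horizontal normals).
    """
    n_pts = len(cloud)
    if k < 3:
        raise ParameterError(f"k must be >= 3, got {k}")
    if n_pts < k + 1:
        raise ParameterError(f"cloud has {n_pts} points, need at least k+1 = {k + 1}")
    tree = cKDTree(cloud.xyz)
    _, nbr = tree.query(cloud.xyz, k=k + 1)
    pts = cloud.xyz[nbr]                      # (N, k+1, 3) incl. the point itself
    centered = pts - pts.mean(axis=1, keepdims=True)
    cov = np.einsum("nij,nik->njk", centered, centered) / (k + 1)
    evals, evecs = np.linalg.eigh(cov)        # ascending eigenvalues
    normals = _orient(evecs[:, :, 0])
    total = evals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        curvature = np.where(total > 0, evals[:, 0] / total, 0.0)
    curvature = np.clip(curvature, 0.0, None)
    return NormalsField(normals=normals, curvature=curvature, k_neighbors=k)


def region_growing(
    cloud: PointCloud, normals: NormalsField, params: RgsParams = RgsParams()
) -> SegmentationResult:
    """Grow smooth-surface clusters from low-curvature seeds.

    Points are visited in ascending curvature order.  Each unclustered point
    starts a region and is pushed as a seed; expanding a seed admits its k-NN
    neighbors whose normal deviates from the *seed's* normal by less than the
    smoothness angle, and an admitted neighbor re-seeds the growth when its
    curvature is below the curvature threshold.  Regions smaller than
    ``min_cluster_size`` are relabeled as noise (-1).  The largest surviving
    cluster is designated soil (ties broken toward the lower label id).
    """
    n_pts = len(cloud)
    if n_pts == 0:
        return SegmentationResult(labels=np.empty(0, dtype=np.intp),
                                  soil_label=UNCLUSTERED, cluster_sizes={})
    if normals.normals.shape[0] != n_pts:
        raise ParameterError("normals were computed on a different cloud")
    k = params.k_neighbors
    tree = cKDTree(cloud.xyz)
    _, nbr = tree.query(cloud.xyz, k=min(k, n_pts - 1) + 1)
    nbr = nbr[:, 1:]
    cos_thr = np.cos(np.deg2rad(params.angle_threshold_deg))
    nrm = normals.normals
    curv = normals.curvature
    order = np.argsort(curv, kind="stable")
    labels = np.full(n_pts, -2, dtype=np.intp)  # -2 = unvisited
    next_label = 0
    for start in order:
        if labels[start] != -2:
            continue
        labels[start] = next_label
        queue = deque([start])
        while queue:
            seed = queue.popleft()
            cand = nbr[seed]
            cand = cand[labels[cand] == -2]
            if cand.size == 0:
                continue
            ok = cand[(nrm[cand] @ nrm[seed]) > cos_thr]
            if ok.size == 0:
                continue
            labels[ok] = next_label
            queue.extend(ok[curv[ok] < params.curvature_threshold].tolist())
        next_label += 1
    # demote small regions to noise
    sizes: dict[int, int] = {}
    ids, counts = np.unique(labels, return_counts=True)
    for lid, cnt in zip(ids, counts):
        if cnt < params.min_cluster_size:
            labels[labels == lid] = UNCLUSTERED
        else:
            sizes[int(lid)] = int(cnt)
    if sizes:
        best = max(sizes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    else:
        best = UNCLUSTERED
    return SegmentationResult(labels=labels, soil_label=best, cluster_sizes=sizes)


def ransac_plane(
    cloud: PointCloud,
    distance_threshold_mm: float = 2.5,
    max_iterations: int = 1000,
    rng_seed: int = 0,
) -> PlaneModel:
    """Fit the dominant plane by random sample consensus.

    Each iteration draws 3 distinct points, forms their plane, and counts
    points within ``distance_threshold_mm``.  The best hypothesis is refit to
    its inliers by least squares (smallest principal direction of the inlier
    scatter) and the inlier set is recomputed once.  Reproducible for a fixed
    seed; iterations draw sequentially from one stream, so increasing
    ``max_iterations`` never worsens the consensus.
    """
    pts = cloud.xyz
    n = len(pts)
    if n < 3:
        raise DegenerateGeometryError(f"plane fit needs >= 3 points, got {n}")
    rng = np.random.default_rng(rng_seed)
    best_count = -1
    best_inl: Optional[np.ndarray] = None
    any_valid = False
    for _ in range(max_iterations):
        sample = rng.choice(n, size=3, replace=False)
        p0, p1, p2 = pts[sample]
        normal = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue  # collinear sample
        any_valid = True
        normal = normal / norm
        offset = normal @ p0
        dist = np.abs(pts @ normal - offset)
        inl = dist <= distance_threshold_mm
        count = int(inl.sum())
        if count > best_count:
            best_count = count
            best_inl = inl
    if not any_valid or best_inl is None:
        raise DegenerateGeometryError("all RANSAC samples were collinear")
    # least-squares refit on the consensus set, then one inlier recomputation
    sub = pts[best_inl]
    centroid = sub.mean(axis=0)
    _, _, vt = np.linalg.svd(sub - centroid, full_matrices=False)
    normal = vt[-1]
    normal = _orient(normal[None, :])[0]
    offset = float(normal @ centroid)
    dist = np.abs(pts @ normal - offset)
    inlier_indices = np.flatnonzero(dist <= distance_threshold_mm)
    return PlaneModel(normal=normal, offset=offset, inlier_indices=inlier_indices)


def fixed_height_cut(cloud: PointCloud, z_cut_mm: float) -> PointCloud:
    """The naive baseline: everything at or below ``z_cut_mm`` is soil.

    Kept only for comparison; with bowl-shaped soil any single cut either
    retains soil at the tray sides or deletes low plants in the middle.
    """
    return cloud.subset(cloud.xyz[:, 2] > z_cut_mm)


def extract_plants(
    tray: PointCloud,
    method: str = "rgs",
    rgs_params: RgsParams = RgsParams(),
    ransac_threshold_mm: float = 2.5,
    ransac_iterations: int = 1000,
    rng_seed: int = 0,
) -> PointCloud:
    """Remove the soil surface from a frame-cleaned tray cloud.

    ``rgs``: the largest region-growing cluster is dropped as soil.  Points
    the growth left unclustered are kept with the plants only if they lie
    above the soil cluster's 95th z-percentile (late-germinating small plants
    survive; low-lying noise does not).  ``ransac``: the dominant plane's
    outliers are returned.
    """
    if len(tray) == 0:
        return tray
    if method == "rgs":
        nk = rgs_params.normals_k or rgs_params.k_neighbors
        if len(tray) < max(nk, rgs_params.k_neighbors) + 1:
            log.warning("tray %s too small for RGS (%d points); returning unchanged",
                        tray.source_id, len(tray))
            return tray
        normals = estimate_normals(tray, k=nk)
        seg = region_growing(tray, normals, rgs_params)
        if seg.soil_label == UNCLUSTERED:
            return tray
        soil_mask = seg.labels == seg.soil_label
        z95 = float(np.percentile(tray.xyz[soil_mask, 2], 95))
        keep = ~soil_mask & ((seg.labels != UNCLUSTERED) | (tray.xyz[:, 2] > z95))
        return tray.subset(keep)
    if method == "ransac":
        plane = ransac_plane(tray, ransac_threshold_mm, ransac_iterations, rng_seed)
        mask = np.ones(len(tray), dtype=bool)
        mask[plane.inlier_indices] = False
        return tray.subset(mask)
    raise ParameterError(f"unknown soil segmentation method {method!r}")
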