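# Methods

`canopycount` turns a raw 3D laser scan of a row of plant trays into per-tray
individual-plant counts. This note documents the models and procedures each
stage implements, the parameters that matter, what the synthetic benchmark
does and does not demonstrate, and the numerical choices made where the
design was genuinely open.

## Problem setting

High-throughput phenotyping platforms scan rows of PVC trays (one genotype
per tray) with a line-laser scanner moving overhead, producing point clouds
with a resolution on the order of 0.8 × 0.8 × 0.2 mm (x, y, z). Counting the
plants in each tray is the bottleneck operation: it is done manually in
practice, and it cannot be done by thresholding height because the soil
surface is not flat — trays hold less soil in the middle than at the sides,
and soil levels differ between trays. The pipeline therefore works in five
steps: tray splitting, soil segmentation, rasterization, detection, and
counting/evaluation. All coordinates are millimeters throughout; a single
unit system avoids silent scale bugs.

## Step 1 — tray splitting and frame removal (`tray_split`)

A raw file covers one row of trays lined up along the y axis. The observed
y-extent of the file is divided into `n_trays` equal half-open intervals
(the last closed, interior boundary ties going to the higher-index tray), so
the partition is complete and deterministic regardless of the scan origin.
Each output tray records its native x–y rectangle; frame removal deletes
every point within `frame_width_mm` (default 20 mm, operator-configurable)
of that rectangle's boundary. Reusing the recorded rectangle — rather than
re-deriving a bounding box from the surviving points — is what makes frame
removal exactly idempotent: a recomputed bounding box always passes through
the extremal remaining points, so a second application would keep eroding.

## Step 2 — soil segmentation (`soil_seg`)

Two surface models are implemented; region growing is the default.

**Normal estimation.** Per point, the k nearest neighbors (k-NN rather than
a fixed radius, which is robust to the scanner's anisotropic density) define
a covariance matrix; the normal is the eigenvector with the smallest
eigenvalue, and the surface-variation curvature is λ₀/(λ₀+λ₁+λ₂) with λ₀
smallest (range [0, ⅓], zero on planes). Normals are oriented into the
z ≥ 0 half-space; exactly horizontal normals (|z| ≤ 1e−9) take their sign
from +y, then +x, so orientation is deterministic.

**Region Growing Segmentation (RGS).** Points are visited in ascending
curvature order. Each unvisited point seeds a region grown breadth-first
over k-NN neighborhoods: a neighbor joins when the angle between its normal
and the *expanding seed's* normal is below `angle_threshold_deg` (the
classic seed-comparison variant — deterministic, no running-average drift),
and an admitted neighbor re-seeds the growth when its curvature is below
`curvature_threshold`. Regions smaller than `min_cluster_size` become noise
(label −1). The largest cluster is designated soil (ties to the lower
label id): soil is by far the densest, most contiguous surface in a tray.

Defaults: `k_neighbors=30`, `angle_threshold_deg=3.0`,
`curvature_threshold=1.0` (every admitted point may re-seed; tighten to
≈0.05 to stop growth from crossing sharp creases — the floor-plus-wall
benchmark relies on this), `min_cluster_size=50`. `normals_k` optionally
decouples the normal-estimation support from the growth neighborhood:
normals benefit from a large, smooth support, while the growth reach sets
the minimum vertical separation at which a low canopy remains separable
from soil. The k-NN reach at sampling pitch s is roughly `s·sqrt(k/π)`;
with the default k=30 at a 4 mm pitch that is ≈13 mm, so structures closer
than that to the soil can be absorbed. The bowl-soil comparison experiment
uses `k_neighbors=10, normals_k=30` for exactly this reason.

**Plant extraction under RGS.** The soil cluster is removed. Non-soil
clusters are kept unconditionally. Unclustered points are kept only when
they lie above the soil cluster's 95th z-percentile: late-germinating small
plants poke above the soil and survive, while low-lying sensor noise is
dropped.

**RANSAC plane consensus.** Each iteration draws 3 distinct points from one
seeded generator stream, forms their plane, and counts points within
`distance_threshold_mm` (default 2.5 mm; 1000 iterations). The best
hypothesis is refit by least squares (smallest principal direction of the
inlier scatter) and the inlier set recomputed once. Plants are the
outliers. Because draws are sequential from one stream, a fixed seed is
bit-reproducible and more iterations never worsen the consensus. On
bowl-shaped soil a single plane cannot follow the surface within the
threshold band, so RANSAC characteristically leaves residual soil — the
behavior that motivates preferring RGS; a test asserts this qualitative
ordering rather than pretending both methods are equivalent.

**Fixed-height cut.** `fixed_height_cut` is the naive baseline kept only
for comparison: with a 15 mm bowl, any single cut either retains side soil
or deletes the canopy of plants that germinated late and sit low in the
bowl. The comparison scene pairs the generator's bowl soil with a
hand-placed stemless seedling rosette 14–18 mm above the bowl center —
above the growth reach, below the side soil level — because that is the
geometry in which the trade-off is unavoidable; randomly placed tall plants
rarely realize it.

## Step 3 — SOR and rasterization (`raster`)

**Statistical Outlier Removal.** Per point, the mean distance to its
`k_neighbors` (default 16) nearest neighbors; points more than
`std_multiplier` (default 2.0) standard deviations above the global mean
are removed, order preserved. Removal is anti-monotone in the multiplier.
Note that on any finite uniformly-sampled surface the rim and corner points
have genuinely larger k-NN distances; with small clouds they can sit more
than 3σ above the mean, so "homogeneous density ⇒ nothing removed" holds
for the interior, not the extreme corners.

**Rasterization.** Plant points are projected onto the x–y grid of the
tray rectangle: pixel (col, row) = (⌊(x−x₀)/s⌋, ⌊(y−y₀)/s⌋), row 0 at
minimal y (PNG export flips to top-left origin). Per pixel the maximum z
wins — the scanner views the canopy from above, and mean-z would blur leaf
edges. Heights are normalized per tray over the plant cloud's own [z_min,
z_max] (soil levels differ between trays, so global normalization would
shift colors), then mapped blue → green → red: h=0 → (0,0,255), h=0.5 →
(0,255,0), h=1 → (255,0,0), linear within each half. The map never produces
black, so black is reserved for background — the detector sees exactly zero
texture where no plant exists. A degenerate z range maps everything to
blue.

The direct `rasterize` default is 0.8 mm/pixel, one pixel per point at the
scanner's native pitch. The orchestrated pipeline defaults to
`pixel_size_mm: auto`, which sets the pitch to 1.25 × the median in-plane
nearest-neighbor spacing of the frame-cleaned tray. The cleaned tray (soil
included) is a single sampled surface, so its spacing estimates the scan
pitch; the plant cloud itself would underestimate it, because stacked leaf
layers overlap in projection. Auto sizing keeps one surface sample per
pixel at any scan density — with a hard-coded sub-pitch pixel size the
rasterized canopy disintegrates into isolated pixels and connected-component
detection finds nothing.

## Step 4 — detection (`detect`)

The detection stage is detector-agnostic. The `DetectorConfig` schema
carries the post-processing a production CNN detector is run with: score
threshold 0.5, overlap suppression at IoU 0.2, at most 10 detections per
class (trays hold a small, bounded number of plants), anchor aspect ratios
0.5/1.0/2.0 (validated and stored; they parameterize CNN region proposals
and are unused by the baseline). `load_external_detections` ingests boxes
exported by any trained detector via the shared CSV dialect.

The built-in baseline detector exploits the reserved background: non-
background pixels are labeled as 8-connected components; each component of
area ≥ `min_area_px` (default 25) becomes one box scored
min(1, area/`area_ref_px`) (default 50), so full plants saturate at score 1
while specks fall to the score threshold. Post-filtering is greedy
score-ordered suppression (ties by input order): accept a box only if its
IoU with every accepted box is ≤ the threshold, then truncate. The filter
is idempotent by construction.

## Step 5 — metrics (`evalmetrics`)

A detection is a true positive at IoU threshold t only when its overlap
with an unmatched ground-truth box *strictly exceeds* t (boundary equality
is a non-match); matching is greedy in score order, each detection taking
the unmatched ground-truth box of highest IoU (ties to the lower index).
P = TP/(TP+FP), R = TP/(TP+FN); zero denominators report 0 with a warning.
AP uses 101-point interpolation (mean over recall anchors 0, 0.01, …, 1 of
the max precision at recall ≥ r) — the COCO convention, chosen because the
aggregate metric is the COCO mAP: the mean AP over thresholds 0.50, 0.55,
…, 0.95. Multi-tray evaluation matches per image and pools the score sweep
across images. Missed plants are false negatives in the standard sense; no
true-negative count exists for detection and none is reported.

Counting accuracy is MAPE over trays, `100/n · Σ |C_pred − C_manual| /
C_manual`; trays with a zero manual count are excluded (the ratio is
undefined) and their predicted boxes are reported separately as a
zero-truth false-positive count. The complementary accuracy is 100 − MAPE.

## Synthetic scenes (`synthetic`)

The generator emulates the platform geometry with exact ground truth:
12 trays of 64 × 40 × 42.5 cm per row (the mung-bean configuration) lined
along y; bowl-shaped soil (separable cosine bowl, default depth 15 mm,
level noise 1 mm, base 380 mm) sampled on a jittered grid; a raised tray
frame; 0–8 plants per tray; and a sparse clutter fraction (default 2%)
standing in for scan noise and barcode returns. Plants are a vertical stem
carrying 3–6 elliptical leaf disks (radius 15–35 mm) at random heights along
a 40–200 mm stature — sufficient to exercise segmentation (height
discontinuity from soil) and detection (compact colored blobs), which is
all the pipeline consumes. Plant centers are rejection-sampled at least
2.4 × the maximum radius apart: the spec of the scene requires
non-overlap (≥ 2 ×), and the extra margin keeps adjacent blobs from merging
at raster resolution. One generator stream seeded once, with draws in the
fixed order soil → frame → plants → clutter per tray, makes scenes
byte-identical for identical spec and seed.

The default sampling pitch is 4 mm rather than the scanner's 0.8 mm,
keeping a full 12-tray row near 200k points while every leaf stays tens of
samples wide; all geometric relationships (bowl depth vs. neighborhood
reach, leaf size vs. pixel size) are preserved relative to the pitch.

**What passing the synthetic benchmark shows — and what it does not.** The
generator realizes the geometric difficulties the pipeline is built around
(non-flat soil, low plants, frames, clutter, empty trays), so end-to-end
counting on it validates the segmentation–rasterization–detection contract.
It does not model occlusion from the scanner's 45° view, radiometric
effects, overlapping canopies of neighboring plants, or real leaf shape;
near-perfect synthetic MAPE therefore does not predict field accuracy,
where a trained CNN detector and real labeled scans are required.

## Numerical choices and degenerate inputs

- Ties: equal-size largest clusters → lower label id; equal detection
  scores → input order; equal IoU in matching → lower ground-truth index.
- Degenerate z range in rasterization → all plant pixels blue. Empty plant
  cloud → all-background image of the tray extent.
- Clouds too small for SOR or RGS are passed through with a logged warning
  rather than erroring: a nearly empty tray is a valid result (count 0).
- RANSAC with fewer than 3 points or all-collinear samples raises a
  degenerate-geometry error.
- Per-tray failures in the orchestrated run are isolated into error
  records; the remaining trays complete.

## Known limitations

- The baseline detector cannot separate touching plants (one merged
  component → one box); the paper-grade remedy is an external CNN detector
  fed through `load_external_detections`.
- A single RANSAC plane per tray; multi-plane consensus is out of scope.
- Region growing is sensitive to the ratio of surface separation to
  neighborhood reach; `normals_k`/`k_neighbors` must be chosen with the
  scan pitch in mind (see Step 2).
- Binary PLY, PCD, LAS and mesh formats are not read; ASCII PLY and
  delimited XYZ only.
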