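# canopycount

Individual-plant detection and counting from 3D laser scans of multi-tray
crop canopies.

High-throughput phenotyping platforms scan long rows of PVC trays (one
genotype per tray) with an overhead line-laser scanner, producing dense
point clouds at roughly 0.8 × 0.8 × 0.2 mm resolution. Counting the plants
in each tray — needed to normalize every downstream per-plant trait — is
usually done by hand. It cannot be done by thresholding height, because the
soil surface is not flat: trays hold less soil in the middle than at the
sides, and soil levels differ between trays, so any fixed cut either keeps
soil or deletes low plants.

`canopycount` implements the five-step pipeline that solves this:

1. **Tray splitting** — the scan row's y-extent is divided into *n* equal
   intervals (one per tray) and the tray frames are stripped by an x–y
   margin test.
2. **Soil segmentation** — Region Growing Segmentation over surface
   normals/curvature (the largest smooth cluster is soil), or RANSAC plane
   consensus (soil = inliers) as the alternative.
3. **Rasterization** — Statistical Outlier Removal, then projection of the
   plant points onto the x–y grid; each pixel takes the maximum z of its
   points and is colored by per-tray normalized height: blue (low) → green
   (medium) → red (high), on a reserved black background.
4. **Detection** — a pluggable detector produces scored boxes on the
   rasterized images. A connected-component baseline detector is built in;
   boxes exported by any trained CNN detector can be loaded instead. Either
   way the boxes pass the same post-filter: score threshold 0.5, greedy
   overlap suppression at IoU 0.2, at most 10 detections per class.
5. **Counting and evaluation** — per-tray plant counts, plus the detection
   metric suite:
   IoU = |B_p ∩ B_gt| / |B_p ∪ B_gt|; precision P = TP/(TP+FP); recall
   R = TP/(TP+FN); AP with 101-point interpolation;
   mAP_COCO = (AP₀.₅₀ + AP₀.₅₅ + … + AP₀.₉₅)/10; and counting error
   MAPE% = (100/n) Σᵢ |C_pred,i − C_manual,i| / C_manual,i (accuracy
   reported as 100 − MAPE).

A synthetic scene generator (`canopycount.synthetic`) produces
platform-like scan rows — bowl-shaped soil, tray frames, 0–8 stem-and-leaf
plants per tray, sparse clutter — with exact per-point ground truth, so the
whole pipeline is testable without proprietary scans.

## Worked example

Generate a 12-tray scan row and count the plants in it:

```python
from canopycount import (PipelineConfig, SceneSpec, TrayLayout,
                         evaluate, generate_scene, run_pipeline)

layout = TrayLayout(n_trays=12)                       # 64 x 40 cm trays
cloud, truth = generate_scene(SceneSpec(layout=layout, rng_seed=7))
result = run_pipeline(cloud, PipelineConfig(trays=layout))
report = evaluate(result, truth)

print(f"points in: {len(cloud)}")
for rec, manual in zip(result.trays, truth.per_tray_counts):
    print(f"{rec.tray_id}: predicted {rec.plant_count}  manual {manual}")
print(f"MAPE {report.mape_percent:.2f}%  "
      f"accuracy {report.counting_accuracy_percent:.2f}%  "
      f"mAP_COCO {report.map_coco:.3f}  "
      f"P {report.precision:.3f}  R {report.recall:.3f}")
```

Output:

```
points in: 211168
synthetic_seed7_tray00: predicted 7  manual 7
synthetic_seed7_tray01: predicted 5  manual 5
synthetic_seed7_tray02: predicted 4  manual 4
synthetic_seed7_tray03: predicted 7  manual 7
synthetic_seed7_tray04: predicted 6  manual 6
synthetic_seed7_tray05: predicted 7  manual 7
synthetic_seed7_tray06: predicted 1  manual 1
synthetic_seed7_tray07: predicted 8  manual 8
synthetic_seed7_tray08: predicted 7  manual 7
synthetic_seed7_tray09: predicted 6  manual 6
synthetic_seed7_tray10: predicted 8  manual 8
synthetic_seed7_tray11: predicted 6  manual 6
MAPE 0.00%  accuracy 100.00%  mAP_COCO 0.977  P 1.000  R 1.000
```

Every tray count is exact here: the synthetic plants are well separated and
the baseline detector finds one component per plant. `report` also carries
the per-threshold APs and the per-tray count table (`counts_frame()`).
Real-world accuracy depends on a trained detector for touching or
overlapping plants — see `docs/methods.md` for what the synthetic benchmark
does and does not demonstrate.

The same run from the shell:

```sh
canopycount simulate --seed 7 --n-trays 12 --out sim/
canopycount run --input sim/scene.ply --out results/
```

which writes per-tray PNGs (height-colored rasters), `detections.csv`,
`counts.csv`, and the effective configuration. `segment`, `rasterize`,
`detect`, `count`, and `evaluate` subcommands run individual stages on
saved artifacts; a YAML/JSON config file (`--config`) overrides any stage
parameter (see `canopycount.config`).

## Layout

- `src/canopycount/io_cloud.py` — ASCII PLY / XYZ clouds, VOC-XML / CSV annotations
- `src/canopycount/tray_split.py` — step 1
- `src/canopycount/soil_seg.py` — step 2 (normals, RGS, RANSAC, fixed-cut baseline)
- `src/canopycount/raster.py` — step 3 (SOR, height colormap, PNG export)
- `src/canopycount/detect.py` — step 4 (baseline detector, NMS-style filter, external adapter)
- `src/canopycount/evalmetrics.py` — step 5 (IoU, P/R, AP, mAP_COCO, MAPE)
- `src/canopycount/synthetic.py` — scene generator with ground truth
- `src/canopycount/pipeline.py`, `config.py`, `cli.py` — orchestration
- `docs/methods.md` — models, parameters, numerical choices, limitations
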