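# leafcal

Post-detection leaf phenotyping for time-lapse seedling experiments.

Instance-segmentation networks output one binary mask per leaf per frame —
and nothing else. `leafcal` turns those masks into biology: it merges and
refines the masks, maintains each leaf's identity across the whole image
series, converts pixel counts into physical leaf areas, derives real-time
growth rates, and evaluates segmentation quality. It targets incubator-style
setups where seedlings (the motivating system is okra under NaCl salt
stress) grow in a fixed 4×4 grid and a camera photographs the tray at a
fixed interval for days, with filenames carrying `YYYY-MM-DD-HH-MM-SS`
timestamps. A built-in synthetic scene generator renders growing-leaf image
series with exact analytic ground truth, so the entire pipeline can be
exercised and validated without a trained network or any external data.

## What it computes

**Calibrated leaf area.** With an image of width *ImgWidth* pixels covering
a physical bench width of 250 mm,

    PixelArea (mm²) = (250 / ImgWidth)²
    LeafArea  (mm²) = PixelArea × SumPixel

where *SumPixel* is the foreground pixel count of one leaf's mask.

**Real-time growth rate.** From the timestamps embedded in filenames,

    GrowthRate (mm²/h) = (Area_current − Area_previous) / (t_i − t_{i−1})

over consecutive frames or any user-defined window. Small negative rates
from segmentation jitter are reported as computed (an optional flag clamps
them at zero).

**Cross-frame label tracing.** In the first frame, the 16 grid leaves are
sorted into four rows by centroid Cy, each row sorted left-to-right by Cx,
and assigned IDs 0–15 row-major. In every later frame an instance inherits
the ID of the live track whose latest mask it best overlaps, when that best
IoU exceeds the threshold (default 0.5); conflicts resolve greedily by
descending IoU, and unmatched instances open fresh IDs.

**Mask merging and refinement.** Per-instance masks are resized to source
resolution, refined (Canny edge extraction → periodic cubic B-spline
contour smoothing → morphological closing), merged into one {0, 255} union
raster, and summarized as centroids, bounding boxes and pixel counts.

**Evaluation suite.** P = TP/(TP+FP), R = TP/(TP+FN), F1; AP as the area
under the all-point precision envelope of the PR curve; mAP50 and mAP50-95
(mean over IoU thresholds 0.50–0.95 in 0.05 steps); convolution-layer
complexity FLOPs = 2HW(C_in·K² + 1)C_out and Params = C_in·K²·C_out.

**Validation statistics.** Least-squares agreement between manual and
algorithmic areas: slope, intercept, Pearson r, R², adjusted R², and
residual diagnostics with an omnibus normality test.

## Worked example

Render a synthetic scene (16 leaves, 15-minute cadence, small raster),
track identities, and compute areas and growth rates:

```
$ leafcal simulate --out demo/scene --seed 1 --frames 8 \
      --img-width-px 360 --img-height-px 370
wrote 8 frames to demo/scene
$ leafcal track demo/scene/labels --out demo/tracks \
      --img-width-px 360 --img-height-px 370
tracked 16 leaves over 8 frames -> demo/tracks
$ leafcal speed demo/tracks/tracks.csv --out demo/pheno --img-width-px 360
wrote areas and rates -> demo/pheno
$ head -4 demo/pheno/speed.csv
frame_time,leaf_id,Cx,Cy,pixel_count,area_mm2,growth_rate_mm2_per_h
2025-03-02 12:00:00,0,48.547945,44.041096,73,35.204475,
2025-03-02 12:15:00,0,48.608108,44.040541,74,35.686728,1.929012
2025-03-02 12:30:00,0,48.666667,44.026667,75,36.168981,1.929012
```

Leaf 0 holds 73 pixels at the first frame; at this calibration
(360 px ↔ 250 mm) each pixel is (250/360)² ≈ 0.4823 mm², so its area is
35.2 mm². One frame (0.25 h) later it gained one pixel, a growth rate of
0.4823/0.25 ≈ 1.93 mm²/h. The first frame of each track has no predecessor,
so its rate column is empty. All 16 leaves keep their grid IDs for the
whole series.

The same subcommands run on real detector output: `convert` turns ISAT
polygon JSON into normalized TXT labels, `merge` builds the merged
`mask.jpg` plus per-instance statistics for one frame, `filter` and
`split` curate a training corpus, `augment` produces seeded augmented
copies, and `eval-seg` / `eval-fit` score segmentation quality and
manual-vs-algorithm agreement.

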