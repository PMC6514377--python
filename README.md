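# phenolidar

Field-based high-throughput phenotyping of maize parcels from multi-view 3D
LiDAR scans, for crop scientists and agricultural-robotics engineers who need
parcel-level **row spacing** and **single-plant height** measurements without
walking the rows.

The measurement scenario is a "phenomobile": a ground robot carrying an
annular 64-line LiDAR (vertical field of view −24.8° to +2°, ~2 cm range
accuracy) that stops every ~1 m along the cement path beside a parcel and
records a 360° scan.  Rectangular 0.40 m × 0.30 m landmark plates on tripods,
raised at least 0.1 m above the canopy, serve as registration fiducials.
Because the sensor cannot depress below α = 24.8°, a ground blind zone of
extent

    D = (H + h) / tan(α)

surrounds the robot (H = bracket height, h = LiDAR origin-to-base offset);
with H = 0.91 m and h = 0.25 m the parcel is scanned from beyond D ≈ 2.5 m.

The processing pipeline has four stages:

1. **Landmark detection** — per scan: cut everything below the canopy top,
   cluster the remainder with DBSCAN (octree-accelerated neighbor search,
   adjacency radius E = 0.52 m = the plate diagonal, MinPts = 5), drop
   clusters with vertical extent below *ch* = 0.1 m, extract each plate's
   upper corner (mean x, min y, max z) and interpolate a *virtual landmark*
   — a regular planar grid with the known plate dimensions.
2. **Registration and fusion** — align the pooled virtual-landmark clouds of
   consecutive selected scans: FPFH-feature sample-consensus initial
   alignment (SAC-IA, with a deterministic corner-correspondence fallback),
   refined by point-to-point ICP; compose the transforms into the frame of
   the last scan and merge.
3. **Row spacing** — project the merged cloud onto the horizontal plane,
   histogram each 1 m depth band along the travel axis (2 cm bins), take
   stem-dominated histogram peaks as in-row candidates, fit row lines with a
   Hough transform constrained to 75°–105° from the travel axis (minimum
   support 3), and report adjacent-line distances RS.
4. **Plant height** — around each row line, mesh the cloud into 0.1 m cells;
   cells whose projected point count exceeds a depth-dependent threshold
   (PtsThre = 80 for x ≤ 5 m, 30 for 5 < x ≤ 8 m, 10 beyond) seed plant
   detections; each plant's height is PH = Height_max − Height_min, the
   maximum elevation in the 3×3 cell neighborhood minus the ground reference
   z_min + 0.005 m.

A synthetic field/sensor simulator (`phenolidar.simulate`) generates maize
parcels, plates and per-viewpoint scans with full ground truth, so the whole
pipeline is testable end to end without field data.

## Worked example

Simulate a campaign (20 rows spaced 0.60 m ± 0.02 m, ~0.6 m plants, five
landmark plates, ten observation spots 1 m apart, 2 cm range noise) and run
the full pipeline:

```bash
phenolidar simulate --out data/ --seed 0 --spots 10
phenolidar run --data data/ --out results/
```

which prints

```
selected plots (step=3): [3, 6, 9]
ROI point counts: [14966, 17516, 16505]
landmarks detected per selected plot: [5, 5, 5]
registered plot 3->6: rms=0.0052 m (corners+icp, 3 it)
registered plot 6->9: rms=0.0062 m (corners+icp, 3 it)
merged cloud: 48987 points
analysis crop from dataset config: x=(3.0, 14.2), y=(-8.4, 4.2)
rows: 20 lines, 19 spacings
plants detected: 508
```

and writes `results/summary.txt`:

```
mean DSR: 100.0%
row spacing: R2=0.8110  RMSE=0.0078 m (19 spacings)
plant height RMSE [0.0 <= x < 5.0]: 0.027 m
plant height RMSE [5.0 <= x < 8.0]: 0.022 m
plant height RMSE [x >= 8.0]: 0.023 m
```

Reading: all five plates were detected in every selected scan (DSR, the
detection success rate, is 100 %); consecutive scans registered with ≈5–6 mm
residual on the virtual landmarks; all 20 crop rows were recovered and the
19 adjacent spacings deviate from ground truth by 8 mm RMS; plant heights
are recovered to 2–3 cm RMS, grouped by depth x from the robot path.
Per-item tables land in `results/row_spacing.csv`, `results/plant_height.csv`
and `results/landmark_detection.csv`.

Each stage is also available as its own subcommand (`roi`, `landmarks`,
`register`, `rows`, `heights`), reading and writing ASCII PCD files, so any
stage can be rerun in isolation; the library API in `phenolidar.*` exposes
everything the CLI does.

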