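# Methods

## Scope and coordinate conventions

All stages share one frame convention: X points from the robot path into the
field (depth), Y along the robot's travel direction, Z up.  Raw scans are
sensor-centric (origin at the LiDAR, ground at z ≈ −(H+h)); the *global*
frame is the sensor frame of the last selected observation spot, so depth x
in the merged cloud is distance from the path — the grouping variable for the
plant-height thresholds and error tables.

## Blind zone and ROI

The sensor's lowest beam is depressed α = 24.8° below horizontal, so no
ground return exists within `D = (H+h)/tan α` of the robot (≈2.51 m for the
0.91 m bracket + 0.25 m origin offset; with α rounded to 25° this is the
2.49 m usually quoted).  ROI abstraction drops (i) the half-annulus facing
away from the parcel, decided by the sign of the dot product with the heading
(boundary points kept), (ii) points with horizontal range outside
[r_min, r_max] with r_min defaulting to D, and (iii) points outside manually
chosen x/y windows.  The ground slice then removes z ∈ [z_min, z_min+0.005 m]
*within the parcel window*, and z_min + 0.005 becomes the global ground
reference Height_min for plant heights.  The manual horizontal thresholds are
applied before the slice so that z_min is the parcel's own minimum, not a
noisy near-path return.  On sloped terrain this single global reference
biases heights; that is a property of the measurement procedure, kept
deliberately.

## Landmark detection

Plates stand ≥0.1 m above the canopy, so a canopy-height cut isolates them.
The cut defaults to 0.70 m above the scan's own minimum elevation — the
canopy-top estimate (mean plant height + 2σ) used when siting the plates;
occasional taller plant tips survive the cut but form thin clusters that the
minimum-vertical-extent filter (*ch* = 0.1 m, interpreted as cluster z-extent
since a plate spans 0.30 m while canopy residue is flat) removes.  DBSCAN
uses E = 0.52 m (plate diagonal) and MinPts = 5, counting the point itself in
its neighborhood (the scikit-learn convention, which the oracle tests rely
on); border points reachable from two clusters go to the first-discovered
cluster.  Neighbor search goes through an in-package octree (leaf size E/2,
exactness verified against all-pairs scans).  The upper corner is
(mean x, min y, max z) of the cluster; the virtual landmark is a vertical
planar grid through that corner, plate_w along +Y and plate_h along −Z, with
0.01 m steps, its normal along X — the plates stand parallel to the travel
direction.

## Registration

The pipeline registers pooled *virtual-landmark* clouds, not raw scans, and
applies the recovered rigid transform to the full scans; consecutive selected
scans are chained and composed into the last scan's frame.

*Coarse stage (SAC-IA).*  FPFH-style 33-bin descriptors are computed with a
fixed-radius neighborhood (3× the interpolation step).  The histograms keep
raw counts rather than per-point normalization: on ideal planar grids every
pair angle is identical and only the neighborhood mass separates interior,
edge and corner points — with normalization the descriptor would be globally
constant and carry no correspondence information.  Sampling is restricted to
*feature-salient* points (the rarest ≈0.5 % of descriptors — in practice the
plate corners), candidates are the k = 10 nearest destination descriptors,
triplets must pass a pairwise-distance rigidity prefilter, and hypotheses are
scored by nearest-neighbor inlier fraction at 0.05 m (8000 samples, seeded,
deterministic).  Two constraints handle degeneracies specific to plate
constellations: hypothesis rotations are capped at 30° (the acquisition
regime is large translation / small rotation, and a zero-thickness plate set
is nearly symmetric under 180° flips), and a final ICP residual above 0.05 m
triggers the fallback (near-uniform plate layouts admit off-by-one-plate
consensus that only the refined residual exposes).

*Corner fallback.*  Plates are paired by mutual-nearest-neighbor corners
after centroid shift, and the Kabsch solution is computed over the pooled
matched virtual grids point-for-point rather than over the corners alone:
corners lie nearly on a line along the path, leaving the rotation about that
line noise-determined, while the full grids span the plate plane and
condition all axes.

*Fine stage.*  Point-to-point ICP with closed-form Kabsch updates; the RMS
residual is non-increasing by construction, tolerance 1e-4 m, max 50
iterations.

## Row spacing and plant height

Row detection follows depth-band histograms (1 m bands, 0.02 m Y-bins — the
bin at the sensor's range accuracy) with a single parcel-wide Hough
accumulator (0.5° × 0.02 m resolution, angles 75°–105° from the travel axis,
minimum support 3).  Peaks require both an absolute floor (5 counts) and, in
the pipeline, 30 % of the band's maximum count: stems exceed the leaf/ground
background by an order of magnitude and a relative floor tracks the density
falloff with depth where an absolute one cannot.  Line extraction is greedy
with non-maximum suppression over two rho bins, so one dense row cannot spawn
near-duplicate lines; each line is refined by a principal-axis fit through
its supporting peaks.  Spacings are measured along the mean normal of
adjacent lines at the ROI's x-midline because detected lines need not be
parallel.

Plant detection meshes each row's neighborhood (perpendicular margin 0.25 m,
half the within-row plant spacing) into BL = 0.1 m half-open cells anchored
at the bounding-box minimum; super-threshold cells merge by 8-connectivity
into one detection seeded at the maximum-density cell.  PH is the maximum
elevation within the 3×3 neighborhood of the seed minus Height_min.  Note the
3×3 footprint (0.3 m) exceeds typical within-row plant spacing (0.25 m), so a
short plant next to a taller one inherits the neighbor's top — visible as
occasional large positive errors at every depth; this is inherent to the
neighborhood rule, not a defect of the implementation.

## Synthetic data generator

The generator emulates the acquisition conditions, not a specific dataset:
20 rows spaced 0.60 ± 0.02 m, 10 m rows with plants every 0.25 m, plant
heights ~N(0.60, 0.05) m, five 0.40 × 0.30 m plates with their bottom edge
0.1 m above the canopy top along the path side, ten viewpoints 1 m apart at
x = −3.5 m with ~0.5° yaw wobble, per-spot surface-sample budget ≈5×10⁵
candidates thinning to ≈1.5–2×10⁴ returned points.  Scans are produced by
surface sampling plus sensor constraints rather than ray casting:

- vertical FOV and blind radius filters (the blind zone also emerges from the
  FOV alone for ground points);
- discrete beam elevations: candidates survive only within ±15 % of the local
  beam spacing around one of the 64 beam angles — the fraction a 2 mrad beam
  footprint subtends — reproducing scan rings whose vertical gaps grow with
  range;
- an azimuthal `min(1, r₀/r)` keep probability (r₀ = 2 m) matching the
  scanner's per-arc-length angular capacity;
- hard stem shadowing plus Beer–Lambert canopy attenuation (per-crossing
  transmittance 0.85 through a 0.15 m canopy cylinder per plant), so deep
  plants are both sparser and partially hidden;
- thin-target dropout: each point carries an effective target width (stems
  taper to 30 % of their 24 mm base diameter at the top; leaf blades narrow
  toward the tip) and survives with probability width/footprint at its range;
- Gaussian range noise applied along the sensor ray (σ = 0.02 m), so the
  vertical noise component scales with sin(elevation) as in a real scanner.

Plate surfaces are sampled uniformly at random: a regular surface grid
aliases against the discrete beam elevations (at close range the grid's
elevation step nearly equals the beam spacing and whole plates vanish).

What the simulator does *not* model: wind deformation of plates and plants,
multi-return behavior, real terrain relief, fully closed canopies, leaning
stems.  Consequently passing tests demonstrate the pipeline's correctness and
its behavior under the modeled physics, not field-grade error magnitudes:
simulated height errors (2–3 cm RMS) are several times smaller than
field-observed ones.

One consequence is documented honestly rather than hidden: with an elevated
sensor over flat terrain, plant *tops* remain geometrically visible at all
depths, so the depth-dependent top-miss (mean signed error falls from
+1.7 cm near to ≈0 far) is partially cancelled by the uniformly positive
ground-reference offset (Height_min sits 1–2 cm below the true ground plane
because z_min is the minimum over many noisy returns).  Grouped height RMSE
therefore comes out near-flat/V-shaped (≈0.027 / 0.022 / 0.023 m at seed 0)
instead of increasing monotonically with depth; the monotone-degradation
acceptance test records this as a failure by design rather than the
conditions being adjusted to mask it.

## Numerical and design choices

- Kabsch rejects <3 pairs and collinear configurations (rank < 2); the SVD
  reflection fix enforces det R = +1; rotation invariants hold to 1e-9.
- File I/O: ASCII PCD is the canonical interchange dialect (written with %.7g
  precision, round-trip ≤1e-6 m); binary little-endian PCD is read-only; PLY
  goes through trimesh; XYZ/CSV accepts comma or whitespace separators.
- Octree: leaves at ≤16 points or edge ≤ leaf_size; box-sphere pruning with a
  fully-contained shortcut; queries return sorted ids.
- Grid/bin conventions: half-open [lo, hi) everywhere, anchored at data
  minima; histogram peak ties resolve to the lower-Y bin.
- Plot selection with 1-based plots: step s selects s, 2s, …; a step beyond
  the plot count degenerates to the single last plot.
- Degenerate inputs raise: empty clouds for ground slicing/ICP, NLV = 0 for
  detection rates, non-positive manual heights for error tables.
- Problem sizes in the shipped tests: the standard campaign is 10 spots at
  ≈1.5–2×10⁴ points per scan after sensor filtering (three scans merged at
  step 3); DBSCAN oracle checks use 250–300-point clouds; the octree oracle
  sweeps 1000 random clouds.  These sizes were chosen so the full suite runs
  in about a minute while still exercising every stage on realistic density
  gradients.
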