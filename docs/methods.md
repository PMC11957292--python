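# Methods

This note documents the models, conventions and design choices behind
`phasetrack`, in the order data flows through the pipeline.

## Segmentation

A phase-contrast frame is reduced to cell regions by a fixed chain:

1. Gradient magnitude √(Gx² + Gy²) of the two 3×3 Sobel kernels
   (x rightward, y downward), borders handled by edge replication so a
   constant image yields an exactly zero map.
2. Binarization at a user-supplied `edge_threshold`, strict `>`. The
   threshold is adjusted once per acquisition setup and then held fixed
   across frames and cell types. When omitted, an Otsu threshold on the
   gradient histogram is used; this automatic default is a convenience
   extension, not part of the core chain.
3. Dilation by an octagonal structuring element, hole filling, then two
   erosions by a diamond structuring element. The pixel sets are frozen:
   octagon r = 3 is {max(|x|,|y|) ≤ 3 and |x|+|y| ≤ 4} (origin-to-side
   distance 3 along the axes, 1.95 µm at 0.65 µm/px); diamond r = 5 is
   {|x|+|y| ≤ 5} (origin-to-vertex distance 5, 3.25 µm). Erosion treats
   out-of-frame pixels as foreground so a cell clipped by the frame or ROI
   border is not eaten from that side.
4. 8-connected components with area ≥ `min_area_um2` (default 200 µm²)
   are kept. Spread cells measure roughly 1 900–2 250 µm², so the default
   rejects edge-noise blobs an order of magnitude below any cell while the
   stop rules stay sensitive to real objects.
5. Each component is smoothed by its convex hull: the polygon of the
   smallest convex set containing the pixel centers, filled at pixel
   centers. Area, equivalent circle diameter 2√(A/π), centroid and major
   axis are measured on the filled hull. The hull deliberately bridges
   thin concavities; constricted shapes are therefore merged, which is the
   desired behaviour for sparse, non-contacting cells.

**Centroid convention.** The centroid is the arithmetic mean of the
filled-hull pixel coordinates. In the default `pixel` mode it is rounded
to the nearest integer pixel, half away from zero; `subpixel` mode keeps
the mean. Pixel mode is the default because 1-min centroid displacements
of adherent cells are of pixel order, and integer centroids reproduce the
grid quantization visible in real turn-angle histograms (see
*Discretization artifact*). Coordinates are 0-based, x rightward,
y downward, pixel centers at integers; microns = pixels × `pixel_size`
(default 0.65 µm/px).

**Major axis.** The major axis of the ellipse with the same second
central moments as the filled-hull pixel set: length 4√λ₁ of the larger
eigenvalue of the population covariance of pixel coordinates, orientation
of the corresponding eigenvector mapped to [−90°, 90°). The estimator and
the 8-connectivity choice are fixed conventions of this package.

## Tracking

One track per region found in the full first frame. For each subsequent
frame a square ROI of side ⌈`roi_scale` × previous major-axis length⌉
(default scale 2.0) is centered on the previous centroid, translated — not
shrunk — to stay in frame, and re-segmented with the same configuration.

* exactly one qualifying region → its centroid/area/axis extend the track
  (converted to full-frame coordinates);
* zero regions → stop `no_centroid`;
* two or more regions → stop `multiple_centroids`;
* one region whose area exceeds `merge_area_factor` (default 1.8×) times
  the previous area, or whose centroid lies farther than half the ROI side
  from the previous centroid → treated as a contact/mismatch, not the
  tracked cell.

The area-jump rule exists because a cell–cell contact can fuse two cells
into a *single* hull; without it a merge would be tracked as one large
cell. No gap closing and no re-acquisition: frames are processed strictly
sequentially and a stopped track stays stopped, so results are
deterministic and contact-free by construction. Only points collected
before a stop event are kept. Tracks whose duration is strictly greater
than `min_track_duration_min` (default 60 min) enter the analysis.

## Motility parameters

For a trajectory p₀…pₙ at constant spacing Δt (default 60 s), with
displacement vectors rᵢ = pᵢ − pᵢ₋₁:

| parameter | definition | units / normalization |
| --- | --- | --- |
| mean speed | mean |rᵢ|/Δt | µm/s |
| turn angle θᵢ | atan2(|rᵢ × rᵢ₊₁|, rᵢ · rᵢ₊₁) | degrees in [0, 180] |
| freq. turns < 90/60/30° | count of θᵢ < threshold, excluding zero-step angles | per 30 h |
| migration distance between turns | total path length / count of qualifying turns | µm (raw) |
| sum of turn angles | Σθᵢ | degrees per 30 h |
| quiescent time | Δt × count of steps with speed < the cell's own mean speed | s (raw) + fraction |
| total migration length | Σ|rᵢ| | µm per 30 h |

Conventions, fixed and tested:

* **Zero-step rule.** If either adjacent displacement is the zero vector,
  θᵢ = 0 and the angle is flagged; flagged angles are excluded from turn
  counts and the distance-between-turns denominator but contribute 0 to
  the sum of angles.
* **Strict inequalities.** "Below" a threshold and "slower than average"
  are strict `<`; ties go to the non-event side.
* **30 h normalization** applies to the three time-extensive parameters
  (turn frequencies, sum of angles, total length): (raw / duration_h) × 30.
  Distance between turns is a per-event mean and stays raw; quiescent time
  is reported raw plus as a fraction of track duration.
* **Distance between turns** is defined as total path length divided by
  the number of qualifying turns. A per-gap mean between consecutive
  qualifying turns would be an equally defensible reading; the per-count
  definition is used because it makes "fewer sharp turns ⇒ longer distance
  per turn" hold arithmetically and is the one frozen in the tests. Tracks
  with no qualifying turn get a missing value, excluded from population
  averages and dropped (with a logged count) from any fit using that
  column.
* **Quiescence threshold** is the cell's own mean step speed, not a
  population mean, so the parameter measures within-track speed
  heterogeneity.
* "Time to stop" and "quiescent time" are treated as the same quantity;
  only the latter name is used.

By construction, total migration length per 30 h = mean speed × 108 000 s;
this identity is asserted in the tests. All ten parameters are invariant
under rigid rotation and translation of the trajectory.

## Discrimination

Two labelled populations (positive = the cancer-like class 1). Pearson
correlations use per-cell parameter values within each group. Group
differences per parameter use the two-sided Welch t-test
(Welch–Satterthwaite degrees of freedom).

Classification uses squared Mahalanobis distances to the class means,
d²ᵢ(x) = (x − x̄ᵢ)ᵀ Sᵢ⁻¹ (x − x̄ᵢ), with the sample covariances (ddof = 1)
and, for LDA, the pooled estimator
S = ((n₁−1)S₁ + (n₂−1)S₂)/(n₁+n₂−2) shared by both classes. A point is
assigned to the nearer class; an exact tie goes to the positive class.
Priors are equal, costs equal, and no log-determinant term is used — the
rule is purely distance-based, so LDA and QDA agree exactly whenever
S₁ = S₂ (a tested identity) and decisions are invariant under any common
affine rescaling of the features. Singular or non-positive-definite
covariances raise a fit error suggesting a different parameter pair.

Performance is summarized by sensitivity tp/(tp+fn), specificity
tn/(tn+fp) and accuracy (tp+tn)/n. Generalization is estimated by
stratified, seeded 10-fold cross-validation (default seed 0); per-fold
rates are averaged. Stratification is a deliberate choice: with 50-cell
classes, unstratified folds can be degenerate. `pair_search` evaluates all
45 unordered parameter pairs per model kind and ranks by accuracy, ties
broken by sensitivity then lexical pair name. The `DiscriminantAnalysis`
facade wraps fit + resubstitution + CV into a results object with a
`summary()` table and a sampled d₁² = d₂² boundary polyline for plotting.

## Synthetic generator

The generator provides ground truth, not biophysical realism.

**Trajectories** follow a persistent random walk: heading increments are
wrapped-normal with concentration κ (sd = 1/√κ rad for κ > 0; κ = 0 draws
a fresh uniform heading each step, giving a mean turn angle of exactly
90°), and step length = speed × Δt. Speed follows either a two-state
Markov chain (defaults v_high = 0.06, v_low = 0.013 µm/s, switch
probabilities 0.05 up / 0.25 down per step — transient bursts about 1/6 of
the time, stationary mean ≈ 0.021 µm/s) or a constant level with Gaussian
jitter (default 0.015 ± 0.004 µm/s). The presets mirror the two reported
phenotypes at their reported scale: a bursty, broadly turning cancer-like
population (two-state, κ = 0.5; mean speed ≈ 1.4× the fibroblast preset)
and a homogeneous slow, directionally persistent fibroblast-like
population (constant, κ = 8). Each trajectory carries a ground-truth
record (expected mean speed from the stationary distribution, expected
mean turn angle from the heading kernel).

**Scenes** draw each cell as an ellipse (default semi-axes 26 × 20 µm,
≈ 1 600 µm² spreading area) with a faint interior offset (+10 intensity
units), a bright halo rim (+60 over ~2 px) and optional low-contrast
protrusions, on a uniform background (level 100) with additive Gaussian
noise (sd 2). Acquisition defaults are 0.65 µm/px and 60 s intervals. The
renderer writes per-frame ground-truth centroids. What it does **not**
emulate: Zernike phase optics (no shade-off, no spatially varying halo),
intensity drift, focus changes, cell deformation, division, or
heterogeneous morphology. Tests passing on rendered scenes therefore
demonstrate the correctness of the algorithmic chain, not robustness to
every real-microscopy artifact; the manually tuned edge threshold remains
the user's responsibility on real data.

All randomness flows from explicit integer seeds; identical seeds give
bit-identical stacks and tables.

## Calibration experiments and problem sizes

The test suite runs three end-to-end calibrations at desk scale, chosen to
keep the full suite under a minute of compute while leaving Monte-Carlo
error well inside the asserted bands:

* **Null**: two populations drawn from the same constant-speed spec
  (0.015 µm/s, κ = 2, 50 cells/group, 180 min tracks). A single 100-cell
  draw has a CV-accuracy standard deviation of ~5 points, so the
  calibration is measured as the mean over five independent draws; it must
  lie within 50 % ± 5 points.
* **Separated**: speed ratio 2 (0.030 vs 0.015 µm/s) and persistence
  ratio 4 (κ = 8 vs 2) must give ≥ 95 % CV accuracy.
* **Pair ranking**: a feature table in which only
  (freq. turns < 30°, sum of turn angles) carries class signal — the ten
  parameters cannot be decoupled at the trajectory level, so this check is
  constructed at the feature level — must rank that pair first among 45.

Tracking ground truth uses a 61-frame, 512×512 px scene with five
non-contacting cells (mean centroid error ≤ 1 px, no premature stops) and
a scripted two-cell contact at frame 30 (stop with the 30 prior points
intact). Oracle checks compare the vectorized geometry and morphology
against brute-force reference implementations (double-loop convolution,
shift-set morphology, BFS hole filling, arccos angles, loop Mahalanobis).

## Discretization artifact

With pixel-mode centroids, per-minute displacements are integer pixel
vectors; for sub-pixel motion they fall on the 8-neighbour grid, so turn
angles concentrate at 0°, 45°, 90°, 135° and 180°. The pooled turn-angle
histogram of rendered-scene tracks reproduces these maxima, matching the
pattern reported for real data at the same sampling. Subpixel mode removes
the artifact at the cost of admitting segmentation jitter as apparent
motion.

## Known limitations

* Segmentation assumes sparse, non-touching cells; contact ends a track
  by design and no lineage is reconstructed after division.
* The edge threshold is per-setup and manual (Otsu default is a fallback,
  not a calibration).
* The ROI side rule (2× major axis) and the merge area factor (1.8×) are
  package conventions; the underlying method constrains only that the
  window is derived from the previous centroid and major axis.
* Real-data discrimination performance for specific cell lines depends on
  recordings this package does not ship; the synthetic calibrations above
  are the properties the tests verify.
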