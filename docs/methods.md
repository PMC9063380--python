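# Methods

## Scope and model

`phenocloud` measures organ-level traits of a single plant from a dense
surface-sampled 3D point cloud. The pipeline assumes a metric,
centimetre-scaled, z-up cloud of one plant (stem plus leaves), as produced
by a structure-from-motion reconstruction after external scale
calibration; reconstruction itself is out of scope. All geometry is pure
point-set processing — no meshes, normals, or learned models.

## Pre-processing

- **Statistical outlier removal.** For every point, the mean distance to
  its k nearest neighbours; points whose statistic exceeds
  `mean + std_ratio · std` of the global distribution are dropped.
  Defaults k = 16, std_ratio = 2.0, standard practice for photogrammetric
  clouds whose artefacts are isolated points far from any surface.
  Survivor order is preserved, and the filter can only remove points, so
  the output stays inside the input bounding box.
- **Ground-plane removal** (off by default). RANSAC plane consensus
  (250 iterations, seeded and hence deterministic) followed by an SVD
  refit on the consensus set. The plane is removed only if it captures at
  least `min_inlier_fraction` of points **and** its normal is within 30°
  of vertical — a plant-only cloud passes through unchanged, and walls or
  planar leaves are not mistaken for ground.
- **Voxel downsampling** (optional). One centroid per occupied voxel,
  grid anchored at the cloud's minimum corner so the operation is
  translation-covariant up to one voxel and reproducible.

## Segmentation

Two points are adjacent when their distance is **strictly** below the
radius threshold r_th; clusters are connected components of that graph,
so the minimum distance between two clusters is ≥ r_th. The implementation
uses a k-d tree (`scipy.spatial.cKDTree.query_pairs`) with an explicit
strict-distance filter and is contractually identical to exhaustive
search; the test suite checks equality against a brute-force
connected-components oracle on hundreds of random instances.

**Radius selection.** Cluster count is recorded on a geometric grid of 25
radii spanning 0.5×–20× the median nearest-neighbour distance. Below the
organ scale the cloud is fragmented and the count falls rapidly; past the
smallest inter-organ gap organs merge; in between the count is stable at
the organ count. `select_radius` returns the smallest radius of the
longest constant-count run (ties go to the smaller radius). Runs with
count zero — every component below `min_cluster_size` — are not usable
segmentations and are excluded from the search; on sparse noiseless
clouds such a run can otherwise outlast the organ plateau.
`min_cluster_size` defaults to 30 points, which suppresses noise
fragments; clusters below it go to a residual set.

**Organ labelling.** The stem is the cluster maximising
`linearity × vertical extent`, where linearity = (λ₁−λ₂)/λ₁ from the
covariance eigenvalues and vertical extent is the span along the up axis.
Stems are elongated and gravity-aligned; leaf blades are planar and
shorter vertically. Remaining clusters are leaves, sorted by the height
of their point nearest the stem (the attachment). Touching leaves are not
split — they surface as one merged cluster and a leaf-count mismatch
warning downstream.

## Trait measurement

- **Apex and stipule.** The leaf's exact farthest point pair (convex-hull
  pruned for large leaves, verified maximal); the member nearer the stem
  cluster is the stipule. Requires ≥ 5 points; smaller leaves are skipped
  with a warning rather than crashing the plant.
- **Midrib polyline.** Leaf points are projected on the apex–stipule
  axis; the range is split into `n_internal + 1` equal intervals and each
  internal point is the centroid of the points in a slab half an interval
  wide around the interval boundary (empty slab: nearest point to the
  boundary plane). For a laterally symmetric lamina the slab centroid
  lies on the midrib, so the construction is noise-robust and reduces to
  the chord for flat leaves. `n_internal` defaults to 5; on circular-arc
  midribs the chord sum of points equally spaced along an arc of turning
  θ undershoots the true arc by the factor `sin(θ/(2(n+1))) / (θ/(2(n+1)))`
  — ≤ 1.2% at n = 5 for θ ≤ 180° — and equal-projection spacing is within
  ~1% of the arc up to θ = 150°. Leaf length is the sum of segment
  lengths, so it always dominates the apex–stipule chord.
- **Leaf width.** Per the band construction: 25 equal intervals of
  projection onto the apex–stipule axis; per band the extreme points
  along the cross axis (second principal direction orthogonalised to the
  apex–stipule axis) give the band width as a 3D distance; the leaf width
  is the maximum over populated bands. Empty bands are skipped; > 40%
  empty bands triggers a warning. All-collinear leaves return width 0
  with a degenerate flag.
- **Stem height.** Bottom = minimal-projection stem point on the stem's
  principal axis (oriented upward); top = the stem point nearest the
  topmost leaf's stipule, or the maximal-projection point if no leaf was
  measured; middle = the point nearest the projection midpoint; height is
  the two-chord length bottom→middle→top (−0.3% on a 30°-bent stem,
  −1.1% at 60°). A `--stem-points` override reproduces manual marking.
- **Leaf count** = number of segmented leaf clusters (one stipule each).

## Synthetic plants and what they do (not) show

The generator builds chilli-like plants from circular arcs because arcs
have closed-form lengths, chords and chord sums, making every measurement
error analytically checkable:

- **Stem**: circular arc of exact arc length S (default regime 5–27 cm),
  bend 0–25°, cylinder radius 0.15–0.4 cm, uniformly sampled surface.
- **Leaves**: midrib = circular arc of exact length L (regime 1.6–6.5 cm)
  with total turning = curl angle; lamina = points offset perpendicular
  to the midrib plane with half-width profile (W/2)·sin(πt)^e, W = L/3 by
  default. Initial inclination U(15°, 40°); golden-angle (137.5°)
  phyllotaxis; the topmost leaf attaches at the stem tip, matching the
  stem-height convention.
- **Vein ridge**: the midrib is additionally sampled as a dense line
  (40 pts/cm, positions uniform at random, exact apex and stipule
  endpoints), emulating the high texture of a protruding vein in SfM
  output and guaranteeing the leaf tip is represented, as it is in real
  reconstructions. Equal spacing is deliberately avoided — it is an
  artificial regularity that creates spurious stability plateaus.
- **Petiole clearance**: leaves attach 1.0 cm off the stem surface; the
  thin petiole is treated as unreconstructed (thin structures routinely
  drop out of photogrammetric clouds), which makes organs r_th-separable.
  The analytic minimum inter-organ gap is reported with the truth
  (computed on fixed 0.1 cm-resolution noiseless surface grids, so truth
  never depends on sampling density or noise), and exact-count claims are
  conditioned on gap > r_th.
- **Nuisance**: isotropic Gaussian noise (default σ = 0.05 cm), uniform
  outliers in an inflated bounding box (default 1%), optional ground
  disc. Sampling density defaults to 50 points/cm². Each organ consumes
  an independent child stream of the seed, so edits to one organ never
  perturb another's samples and clouds are bit-reproducible.

What passing tests on these plants does **not** show: real SfM clouds
have spatially correlated noise, holes, occlusion artefacts, petioles and
overlapping/touching leaves; the generator models none of these, so
synthetic recovery rates are an upper bound on field performance, not an
estimate of it.

## Experiment sizes and observed behaviour

The packaged recovery experiment pools 58 leaves (the pooled size of the
reference field study) across plants of 3–11 leaves, full pipeline,
seeded. At σ = 0.05 cm it recovers leaf length with MAPE ≈ 2–3% and
R² ≈ 0.996; noiselessly MAPE ≈ 0.4–0.7%, dominated by the chord-sum
shortfall. Stem height lands at ≈ 1–2% MAPE and leaf count is recovered
exactly in the separable regime. These numbers are recomputed, not
stored, by `scripts/acceptance.py` and the test suite.

## Numerical choices and known limitations

- Ties (farthest pair, band extremes, argmin/argmax selections) break to
  the lowest point index, keeping results stable under point reordering.
- All traits are rigid-motion invariant (pass the rotated up-axis) and
  scale equivariantly; reports are written with sorted keys and no
  timestamps, so identical config + seed gives byte-identical files.
- The cross axis for leaf width follows the leaf's second principal
  direction. For strongly curled narrow leaves (curl ≳ 135° at width =
  length/3) the second principal direction rotates from the lamina's
  transverse direction toward the curl's sagitta, and width is then
  underestimated; leaf width is accordingly the least accurate trait
  (≈ 15% MAPE in the synthetic regime). A midrib-plane-normal cross axis
  would fix this but is deliberately not the default, to keep the width
  definition a pure function of the point distribution.
- MAPE is undefined when a true value is zero; the metrics raise instead
  of silently dropping pairs.
- Very short stems (< 5 points after segmentation) and leaves with < 5
  points are reported as warnings, not measurements.
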