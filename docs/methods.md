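# Methods

## Problem setting and conventions

The package estimates, from a single aligned RGB-D frame of a fruit
tree, where each fruit is and along which direction a gripper can
approach it without hitting the branch it hangs from.  All geometry is
expressed in the depth camera's frame, in millimetres: `x` right, `y`
down (image rows), `z` along the optical axis.  Pixel coordinates are
0-based `(u = column, v = row)`, and an integer pixel back-projects at
its centre.  A stored depth value is the `z`-coordinate of the surface
seen through the pixel, not the Euclidean ray length; 0 is the sole
invalid marker (NaN and negative values are mapped to 0 at load time).
Depth below the configured minimum working range (550 mm by default,
the closest distance at which time-of-flight readings are trusted)
triggers a warning but is kept: clipping is the caller's decision.

## Segmentation interface

The pipeline consumes any per-pixel class map with codes 0 background,
1 fruit, 2 branch.  Learned segmenters are deliberately out of the
package's scope — they are training-data artefacts, not geometry — so
the interface is a plain 2D label map plus a deterministic colour-rule
baseline (HSV band thresholds) that makes the end-to-end pipeline
runnable on the simulator's RGB previews and on simple field images.
Segmentation quality metrics (per-class mean accuracy `n_ii / t_i` and
IOU `n_ii / (t_i + Σ_j n_ji − n_ii)`) operate purely on 2D maps:
pixels without a valid depth measurement still count there, and only
drop out later at back-projection.  Classes absent from the ground
truth are reported as NaN and excluded from unweighted means.

## Fruit detection

Euclidean clustering joins two fruit points into the same cluster iff
they are connected by a chain of hops each ≤ 4 mm.  The threshold
trades off splitting one fruit (too small) against merging neighbours
(too large); 4 mm suits point clouds whose lateral sample spacing at
typical ranges (0.6–1.2 m) is 1.5–3 mm.  The radius search uses a
kd-tree with *exact* radius queries, so cluster membership is
bit-identical to connected components of the ≤-threshold adjacency
graph — the property the test suite checks against a brute-force
oracle.  Clusters below `min_cluster_size` (default 30 points) are
discarded; pixel-wise segmenters inevitably produce speckle, and a
cluster of a handful of points carries no usable geometry.  Output
order (descending size, ties by smallest member index) and growth
order are fixed so cluster ids are reproducible.

Centre estimation offers three methods:

- `bounding_box`: the cluster mean.  Fast, but biased toward the
  camera on single-view data, since only the front cap of the fruit is
  visible (for a hemispherical cap the bias is about half the radius).
- `sphere_fit` (default): algebraic linear least squares on
  `‖x‖² = 2c·x + (r² − ‖c‖²)`.  On noiseless cap samples this recovers
  the true centre and radius to numerical precision, which removes the
  single-view bias entirely.  Fewer than 4 points or a
  coplanar/collinear design raises a degenerate-fit error and the
  caller falls back to the cluster mean (flagged on the detection).
- `sphere_ransac`: consensus fit (4-point samples, surface-distance
  inliers at 5 mm, 1000 seeded iterations, least-squares refit on the
  winning inlier set) for outlier-contaminated clouds such as
  hand-labelled ground truth.  An optional radius prior rejects
  implausible candidate spheres; with a prior, a model must gather at
  least one point beyond its own minimal sample, so structureless
  clouds fail loudly instead of returning a chance 4-point sphere.

## Branch reconstruction

The branch plane is thinned with the morphological (Lantuéjoul)
skeleton, the union over k of `(A ⊖ kB) − (A ⊖ kB) ∘ B` with a 3×3
square structuring element (8-connectivity; configurable).  The
skeleton is a subset of the mask and leaves 1-pixel-wide lines
unchanged.  Thinning reduces the branch cloud by roughly the branch
width in pixels, which makes the subsequent stage's per-candidate
inlier counting cheap.

Skeleton pixels with valid depth are back-projected and fed to a
sequential RANSAC line detector: per round, 4000 two-point candidates
are drawn (coincident pairs redrawn); each candidate's infinite line
is scored by the number of points within a 15 mm perpendicular tube
(computed via the cross-product identity, chunked for memory); the
best candidate is accepted while its support strictly exceeds 40
points, its inliers are removed, and the next round begins; otherwise
detection stops.  The literal "repeat until the cloud is empty" cannot
terminate once fewer points than the support floor remain, so the stop
rule is the support test itself.  Accepted segments are refined by a
total-least-squares (SVD) line fit on their inliers — switchable off
via `strict_paper_mode`, which keeps the raw two-point model — and
their extent is the min/max of inlier projections.  Directions are
canonicalised to non-negative `z` (ties: `y`, then `x`) so runs are
comparable across seeds.  Inlier sets of accepted segments are
pairwise disjoint by construction.

Two systematic behaviours of this stage matter downstream:

- **Surface-vs-axis offset.**  A single view sees only the branch
  front surface, so the fitted line sits about one branch radius in
  front of the true axis.  The induced pose error is roughly
  `atan(r_branch / stand-off)`: ~5° for a 9 mm-diameter lateral at a
  60 mm stand-off, ~9° for an 18 mm branch.  The synthetic canopy uses
  thin fruit-bearing laterals (4–4.5 mm radius) with 28–30 mm pedicels,
  which is realistic for guava and keeps this bias below the recovery
  tolerances asserted in the tests; thick scaffold branches would not.
- **Bridging.**  The accepted model is the consensus maximum, so when
  one branch's infinite line passes within the inlier tube's reach of
  another branch's points, a tilted candidate can "bridge" both and
  out-score either true axis.  The bundled scenes keep axes >100 mm
  apart everywhere, where bridging is impossible; on real canopies with
  crossing branches it is a genuine failure mode of the method.

## Pose estimation

The mother branch minimises the perpendicular distance of the fruit
centre to each segment's *infinite* line, exactly as the assignment
formula is written.  Because an infinite line extends past its support,
a distant collinear segment can capture a fruit (a known
false-mother-branch failure); `clamp_to_extent=True` instead clips the
projection to the segment's inlier extent before measuring distance.
The nearest branch point is the orthogonal projection
`n = p + ((c − p)·t) t`, and the pose `q = (c − n)/‖c − n‖` is
perpendicular to the branch axis to within 1e-9 by construction.  A
centre within 1e-6 mm of the axis has no defined direction and is
reported as unposed rather than raising mid-pipeline, as are all
fruits when no branch was reconstructed.  Angular pose errors use the
clamped arccos of the normalised dot product, so rounding can never
produce NaN; angles are reported in degrees.

## Evaluation

Detection is scored by greedy one-to-one matching of predicted to true
centres in order of increasing distance, within a 30 mm tolerance
(about one fruit radius; configurable).  Greedy matching is
order-independent and exact on separable instances; it is not a
maximum-cardinality matching in adversarial geometries, which is
acceptable for counting well-separated fruits.  Precision is TP over
detections, recall TP over true fruits, with 0/0 reported as NaN.
Pose errors are summarised by MEDE (median) and MAD (median absolute
deviation about the median) — robust to the heavy tail that wrong
mother-branch assignments produce — plus the percentage of errors
strictly below 45°/35°/25°.  Medians of even-length samples are the
mean of the central pair.

## Synthetic scenes

The simulator models what the geometry pipeline needs and nothing
more: branches are finite cylinders, fruits are spheres held off the
branch surface by a rigid pedicel, always perpendicular to the axis —
so the true centre, attachment point, mother branch and pose are known
by construction, not estimated.  Rendering is analytic per-pixel ray
casting (ray–sphere and ray–finite-cylinder, nearest hit wins), and
depth noise is i.i.d. Gaussian on `z`, seeded and clipped positive.

Default camera: 512×424 frame, `fx = fy = 365` px, principal point at
the image centre — representative of a consumer time-of-flight depth
camera.  Presets: `single_fruit`, `two_touching_fruits` (1 mm surface
gap), `three_branch_canopy` (3 branches / 4 fruits, the end-to-end
reference scene), `collinear_2d_depth_split` (two axes on one image
line, 200 mm apart in depth), and `noisy_noon` (the canopy at
σ = 32 mm, the depth-noise level reported for time-of-flight sensors
in direct noon sunlight at ~1 m).

What the simulator does *not* emulate — and therefore what passing
tests do not show about field data: leaves and occlusion, segmentation
errors (labels are rendered, hence perfect), distance-dependent and
correlated sensor noise, multi-path artefacts at concave junctions,
non-spherical fruits and curved branches.  Field performance is
dominated by segmentation quality, which is outside this package.

Two geometric subtleties of rendered spheres are worth recording.
First, the depth gradient at a sphere's silhouette is steep: adjacent
pixels near the rim differ by `≈ √(2 r p)` in depth (p = lateral pixel
pitch), so at the default resolution the outer annulus of a rendered
fruit is disconnected from its cap at a 4 mm hop, and two spheres with
any positive surface gap will *not* merge.  The `two_touching_fruits`
preset therefore uses a narrow-FOV close-range camera (`fx = 730`,
p ≈ 1 mm at 700 mm), under which the documented merge failure occurs
exactly as it does with real sensors at close range.  Second, the cap
points nearest the rim are razor-thin in lateral extent; minimum
cluster sizes below ~10 would admit these slivers as spurious fruits.

## Numerical choices

- Cosines are clamped to [−1, 1] before `acos`; unit-vector checks use
  1e-9; pose degeneracy uses 1e-6 mm.
- RANSAC ties (equal inlier counts) resolve to the first candidate
  drawn, making results a pure function of the seed.
- Sphere and line least squares use `numpy.linalg.lstsq`/SVD with rank
  checks; rank deficiency is an error, not a silent bad fit.
- All randomness flows through `numpy.random.default_rng(seed)`;
  re-running any stage with the same seed reproduces byte-identical
  JSON output.

## Problem sizes used in verification

The bundled scenes render 512×424 frames with 3–7 objects (≈ 2–7 k
labelled points per frame); line-detection tests use 130 points per
axis over 300 mm spans with 2 mm isotropic noise; clustering oracles
run on up to 300 points; sphere-fit checks use 50–200 surface samples.
These sizes exercise every code path at full parameter settings
(4000 candidate draws per RANSAC round) while keeping the whole suite
fast enough to run on every change.

## Known limitations

- Branch lines are straight; strongly curved branches fragment into
  several segments or fail the support threshold.
- The reconstructed line tracks the branch front surface, not its
  axis (bias ≈ one branch radius toward the camera).
- Mother-branch assignment by nearest line has no notion of "above the
  fruit" or other priors; the clamped mode mitigates, but does not
  eliminate, false assignments.
- Greedy sequential RANSAC can bridge branches whose axes approach
  within the inlier tube's reach.
- Depth noise at the σ = 32 mm level defeats 4 mm clustering entirely
  (neighbouring pixels separate by many hops); this mirrors the
  documented noon-sun failure of time-of-flight sensing and is
  observable with the `noisy_noon` preset.
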