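# Methods

This note documents the models and procedures implemented in `swmlabel`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic validation does and does not show.

## Fiber representation and distance

All comparisons operate on fibers resampled to **K = 21 points at equal
cumulative arc length** (linear interpolation along the source polyline, no
smoothing; the first and last points equal the source endpoints exactly).
The **minimum average direct-flip (MDF)** distance between two resampled
polylines is the mean Euclidean distance between corresponding points,
minimized over the two possible point correspondences (direct and
reversed). Taking the minimum makes the distance independent of the
arbitrary storage direction of tractography streamlines; it is symmetric,
non-negative, and invariant under rigid motion applied to both fibers.
Degenerate inputs: a zero-length polyline cannot be resampled and raises a
dedicated error rather than returning NaNs.

## Stage 1 — whole-brain fiber clustering

A scalable four-step scheme:

1. **Point clustering.** Mini-batch k-means (scikit-learn; batch 1000,
   10 iterations, k-means++ seeding from the run seed) on the 3D point
   clouds at positions {0, 5, 10, 15, 20} of the resampled fibers. The
   positions are independent and could run concurrently; each position uses
   its own deterministic seed (base seed + position index), so parallel and
   sequential execution give identical labels.
2. **Preliminary clusters.** Fibers sharing the whole label tuple form a
   cluster. Because fibers may be stored in either direction, a tuple is
   canonicalized to `min(tuple, reversed(tuple))` before grouping — without
   this, one anatomical bundle splits by storage order. This requires the
   position subset to be symmetric about the fiber midpoint (the default
   is).
3. **Reassignment.** Clusters below `min_preliminary_size = 3` fibers merge
   into the nearest large cluster if the centroid MDF is ≤ 6 mm, else they
   survive as-is (and usually die in stage-2 filtering).
4. **Merging.** Candidate clusters sharing the label at the central
   position (index 10) whose centroid MDF is ≤ 8 mm are united by
   single-linkage transitive closure; centroids are recomputed.

`k_points` defaults to `min(200, n_fibers / 50)`. The choice matters: when
k is much larger than the number of natural point blobs, blobs split at the
*central* position and step 4 can no longer merge the pieces (it requires a
shared central label). The adaptive default keeps k near the expected
bundle count for both desk-scale cohorts and million-fiber tractograms.
None of the four thresholds is canonical; all are exposed in
`ClusteringParams`.

**Cluster centroid**: members are co-oriented against the first member
(flip when the flipped mean pointwise distance is smaller) and averaged
pointwise. The result is independent of the members' storage directions as
long as the reference member's orientation is fixed.

## Stage 2 — filtering

Keep a cluster iff `n_fibers ≥ 10` and the *centroid's* polyline length is
in **[30, 80] mm**, boundaries inclusive. Length is measured on the
centroid, not as a per-fiber mean: jitter inflates individual fiber lengths
but cancels in the pointwise mean, so the centroid length is the stable
quantity. The filter is idempotent by construction.

## Stage 3 — mesh intersection

A uniform grid with **1.5 mm** cells covers the mesh bounding box; every
triangle is registered in each cell its axis-aligned bounding box overlaps
(conservative — lookups can return false candidates but never miss one).
For each fiber extremity the search segment runs from the adjacent
resampled point (one point inside the fiber) to a linear extrapolation two
point-spacings beyond the endpoint along the local direction; candidates
are the triangles in the cells of the four segment sample points plus their
26-neighborhoods. Each candidate is tested with the Möller–Trumbore
solution of `O + tD = (1−u−v)V0 + uV1 + vV2`; a hit requires `u ≥ 0`,
`v ≥ 0`, `u + v ≤ 1` and `t` within the segment (origin at the endpoint,
`t ∈ [−d, 2d]` for local spacing `d`). Among multiple hits the one with the
smallest `|t|` (closest to the endpoint) wins, ties to the lowest triangle
index. Determinant magnitudes below 1e−12 are treated as parallel;
genuinely degenerate triangles additionally warn. The grid path is tested
for exact agreement with an all-triangle scan.

The extrapolation step length is the local resampled point spacing — the
backward reach is therefore one spacing (~2–3 mm for bundles in the filter
band) and the forward reach two. Fibers terminating more than one spacing
*outside* the mesh, or more than two spacings inside, are not intersected;
that is the intended behavior, matching how tractography streamlines
terminate near the white–gray boundary.

## Stage 4 — naming

* Triangle region = majority of its three vertex labels; a 3-way tie falls
  to the smallest region index (deterministic).
* Fibers are aligned to the centroid: fiber i flips iff its first point is
  strictly closer to the centroid's last point than to its first. A fiber's
  intersection record swaps init/end when the fiber flips.
* Only fibers with **both** extremities intersecting vote. `mcl_init` /
  `mcl_end` are the modes over start/end triangle regions (ties to the
  smallest region index). The pair is ordered by ascending atlas index —
  inverted bundles are flipped wholesale — and rendered
  `<hemi>_<A>-<B>_<k>`.
* The positional index k orders same-pair bundles by the chosen coordinate
  (default ascending y) of the *centroid's* intersection point in the
  first-named region; ties fall to the next coordinates cyclically
  (y→z→x), then to fiber count descending. If the centroid itself does not
  intersect, its first point anchors the sort instead.
* A bundle with no doubly-intersecting fiber stays unlabeled and is
  excluded from outputs.

## Inter-subject labeling

Bundles are first grouped by `(hemisphere, region pair)`; relabeling never
changes that part of the name.

**Matching.** Within a region pair, subjects are ordered by descending
bundle count (ties by subject id). The first becomes the reference; its
open bundles receive indices from a single per-region-pair counter (which
precludes index collisions across reference iterations). A rectangular
minimum-cost assignment (`scipy.optimize.linear_sum_assignment`, exact) on
the centroid MDF matrix is solved against each later subject's open
bundles; matched pairs with MDF ≤ threshold inherit the reference index,
others stay open. The next subject in order holding open bundles becomes
the next reference, until none remain. Each (subject, label) holds exactly
one bundle. The pairwise assignments are independent per reference — no
joint multi-subject optimization.

**Clustering.** The pooled centroids of a region pair (subjects in id
order, bundles in intra-label order — the pass is order-dependent, so the
order is fixed) are clustered in one online pass: a centroid joins the
nearest existing cluster when the MDF to its running centroid is ≤ the
threshold, else seeds a new one. The running centroid is the incremental
mean of flip-aligned members; clusters are never recomputed, and no
re-assignment pass follows the final merge. Same-subject members of one
cluster are merged (fiber union; centroid recomputed from the union), which
is the characteristic difference from matching: near-duplicate bundles
within a subject collapse to one label here but keep two labels there.

Threshold presets {10, 12, 18, 21} mm span conservative to moderate
similarity; the default is the conservative 10 mm.

## Reporting

Reproducibility of a group-wise label = number of distinct subjects holding
it. The summary counts labels reaching ≥ 50% and ≥ 75% of the cohort
(thresholds on `ceil(p·S)` subjects) and the maximum subject count among
the top-20 labels. Precision is the mean MDF over all unordered
cross-subject centroid pairs per label (undefined/NaN for single-subject
labels). Heatmaps show fiber counts of the top-k labels normalized by the
matrix-wide maximum, with absence rendered as missing, not zero.

## Synthetic cohorts

The generator emulates the three inputs at desk scale:

* **Mesh**: an icosphere (radius 50 mm, subdivisions 3 → 642 vertices)
  parcellated by nearest seed vertex, seeds from farthest-point sampling;
  region indices/names come from the packaged Desikan–Killiany-style table
  (35 regions; PoC=22, PrC=24, …). Defaults use 16 parcels so that 15
  well-separated bundle families exist between parcel pairs with angular
  separation 0.6–1.1 rad (arc lengths ≈ 40–65 mm, inside the filter band).
* **Bundles**: U-shaped arcs between two parcel-center directions
  (spherical-linear interpolation) whose radial profile starts 1 mm *under*
  the surface, dives steeply to 12 mm depth, and re-emerges — endpoints sit
  where real streamlines terminate, and the extremity search segments cross
  the mesh. Copies get Gaussian per-point jitter (default σ = 1 mm) and a
  random storage direction (50% reversed) to exercise all flip logic.
* **Cohorts**: default 5 subjects × 15 families × 30–60 fibers, plus 200
  unanchored low-curvature noise fibers per subject (they are dispersed, so
  they form tiny clusters and die in filtering — mimicking tractography
  artifacts). Each family is rigidly displaced per subject with σ = 2 mm,
  projected onto the tangent plane of the family's mid-direction: variation
  slides bundles *along* the cortex rather than detaching them from the
  shared synthetic surface (with per-subject meshes, real cohorts vary in
  depth too; a single shared mesh cannot represent that). Everything is
  deterministic given the seed; a ground-truth table records each fiber's
  subject, family and parcel pair.

**What passing tests show — and don't.** The synthetic cortex is a sphere:
no folding, no narrow gyral walls, no mesh defects; parcels are convex
caps; bundles are cleanly separated (≥ 12 mm family separation) and noise
is unstructured. Perfect recovery here validates the machinery
(resampling, distances, intersection, voting, both group algorithms and
their contrast), not performance on real tractography, where touching
bundles, partial volume artifacts and registration error will degrade all
stages.

## Problem sizes

The default validation cohort (5 × ~850 fibers, 1280-triangle mesh) runs
the full double-method pipeline in seconds; the clustering scheme and the
grid are the same code paths that scale to millions of fibers via
`k_points` and cell size, but no million-fiber run is part of the test
suite.

## Known limitations

* Orientation canonicalization in clustering step 2 requires a
  midpoint-symmetric position subset; custom subsets that break symmetry
  weaken the reversed-tuple rule.
* QuickBundles-style labeling is order-dependent by nature; determinism is
  achieved by fixing the processing order, not by removing the dependence.
* Bundles whose centroid misses the mesh fall back to the centroid
  endpoint for positional sorting, which can reorder very close same-pair
  bundles.
* The `.bundles` (BrainVISA) dialect and FreeSurfer binary annotation files
  are not parsed; labels must be provided as TSV.
* Registration between subjects is assumed done; only a user-supplied
  per-subject affine can be applied at load time.
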