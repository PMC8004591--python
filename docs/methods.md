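# Methods

## Geometry model and units

All geometry is carried as indexed triangle meshes with vertex coordinates
in millimetres. Submeshes (the plant after preprocessing, individual leaf
clusters) keep a `source_vertex_indices` map back to their parent mesh so
segmentation output can be compared against scene-level ground truth.

## Local surface attributes

Per-vertex normals and curvature come from the covariance of the `n_p`
Euclidean nearest vertices (default `n_p = 30`, the usual neighbourhood
size for fitting a local surface on scanner point clouds): the normal is
the eigenvector of the smallest eigenvalue, and the curvature is the
surface-variation ratio λ_min/(λ₁+λ₂+λ₃) — 0 on planes, at most 1/3 for
isotropic scatter, dimensionless and scale-free. Normals are oriented
away from the mesh centroid; exact ties keep the eigenvector sign, which
is harmless because all downstream comparisons use unsigned angles.

Per-vertex *smoothness* is the mean unsigned angle, in degrees, between a
vertex normal and the normals of its edge-adjacent vertices
(arccos |nᵢ·nⱼ| ∈ [0°, 90°]). The unsigned form avoids the sign ambiguity
of normals on open sheets. ς (mean smoothness) and ρ (mean curvature) are
plain arithmetic means over all plant vertices, computed once on the
preprocessed plant and reused at every segmentation level, so every
level's thresholds are multiples of the same pair.

## Non-plant removal

The table plane is found by RANSAC over random vertex triples (default
1000 iterations, 2 mm inlier tolerance, seeded and bit-reproducible),
refit by total least squares on the consensus set, and oriented so the
off-plane vertex centroid has positive height. A face survives only if at
least one of its vertices reaches signed height ε = 100 mm — conservative
toward keeping leaves that dip near the buffer. The iteration count and
tolerance are engineering defaults; the buffer ε is the printed constant
of the procedure. Connected-component cleanup is deliberately not
performed: stray floaters above the buffer are kept and left for the
cluster-size floor and the shape models to reject.

## Region growing

Clusters grow greedily from the unassigned vertex of minimum curvature
(ties by vertex index, making the whole segmentation deterministic). An
edge-adjacent unassigned vertex joins the cluster when its normal deviates
from the normal of the front vertex it is reached from by at most ε_a; it
becomes part of the growth front only if its own curvature is at most
ε_b. The admission test is local (candidate vs front vertex), the
convention of the region-growing family this method builds on: comparing
against a region-average normal instead would split any leaf whose midrib
bend exceeds the threshold, because the average diverges from the local
normal by half the accumulated bend. Clusters below
`min_cluster_vertices = 50` are discarded outright — stem fragments and
speckle whose traits would be meaningless.

## Multi-level loop

Level t uses ε_a = m_t·ς and ε_b = m_t·ρ with m_t = 1.5 − 0.05(t−1): an
arithmetic schedule anchored at 1.50 and 1.45 for the first two levels,
with an absolute floor of 10⁻⁴ on either threshold and m_t > 0, which
bounds the loop at 30 levels. After each level every sufficiently large
cluster is measured, the two shape models are fitted on all
accepted-so-far plus current clusters, current clusters passing the
detection band are accepted (their geometry is frozen), previously
accepted clusters are re-tested against the refreshed model and may be
dropped, and the geometry of failing clusters is re-segmented at the next
level. When the loop ends, a final model fitted on the accepted clusters
alone re-screens them once more; the survivors are the typical leaves.

One guard supplements the schedule: a failing cluster that a finer level
reproduces with an identical vertex set is retired as unsegmentable
rather than carried further. Tightening thresholds can only shatter such
a cluster into sub-leaf fragments, and a flood of fragments entering the
model pool would drag the population means down far enough to evict every
legitimately accepted leaf. The guard is inert whenever re-segmentation
makes progress.

## Trait measurement

* **Area**: summed triangle areas (half cross-product per face).
* **Perimeter**: total length of edges incident to exactly one face;
  non-manifold edges (≥ 3 faces) raise a topology error.
* **Length**: boundary vertices in the bottom/top q = 0.05 quantiles of
  the projection onto the first principal axis (minimum 3 per end) are
  endpoint candidates; candidate pairs are shortlisted by edge-graph
  shortest-path distance *and* by Euclidean chord (a geodesic lower
  bound), each shortlisted path is pulled tight on the surface, and the
  longest tightened path is the leaf length. Tightening is a multiscale
  curve-shortening flow: resample to uniform arc length, box-smooth at
  geometrically decreasing windows, re-project onto the mesh after each
  sweep (endpoints fixed), then polish with local midpoint relaxations.
  Raw graph paths overestimate diagonal routes by up to ~15 % (taxicab
  zig-zag); after tightening, a strip bent over a half-cylinder measures
  within ~1.4 % of the analytic arc and a flat ellipse within ~0.5 % of
  its major axis. The dual shortlist keeps the measured length
  non-decreasing when q grows in practice, though the discrete selection
  makes that monotonicity empirical rather than provable.
* **Width**: the length path is tightened, resampled at K = 20 evenly
  spaced stations, and at each station the mesh is sliced by the plane
  through the station with normal along the local path tangent (tangent
  taken over a ± L/K arc-length window — a single-edge tangent would
  misorient the plane). The intersection polyline through the station is
  chained from the slice segments; stations with an empty slice fall back
  to the widest chord among vertices near the plane. Width is the maximum
  over stations.
* The six ratio traits are always derived from the stored scale traits,
  never re-measured.

## Shape models and detection

The weights a (4 scale traits) and b (6 ratio traits) are the normalized
eigenvalue spectra — variance contribution rates — of the *correlation*
matrices of the fitting clusters' trait matrices, paired with the traits
in their fixed order with the spectrum sorted descending. Correlation
scaling keeps mm²-valued area from dominating the spectrum; the pairing
convention is deterministic where the defining equations index weights by
trait. With fewer than 5 clusters, or zero variance, the model falls back
to equal weights and is flagged degenerate; a model fitted on fewer than
2 clusters accepts everything (no population to filter against).

As printed, the size test would band F against its own fitting-set mean —
which is identically zero because the means in F come from the same
clusters and the weights sum to one. The detection therefore bands the
shifted score F′ = 1 + F, whose fitting-set mean is exactly 1, against
(0.25, 1.25); this preserves both band constants and the intent of
rejecting leaves far from typical size. G is banded against its
fitting-set mean Ḡ directly, summing the heterogeneous ratio units raw.

A consequence worth noting: with strongly correlated scale traits the
spectrum concentrates (a ≈ (1, 0, 0, 0)), so the size test effectively
bands *area* at (−75 %, +25 %) around the mean. The asymmetric band is
generous to small leaves and strict with large ones.

## Synthetic scenes

The generator emulates what a hand-held scanner delivers for a pothos-like
plant. Leaves are elliptical surfaces (semi-axes 30 × 20 mm by default)
triangulated by Delaunay over a boundary ring plus interior grid, bent
isometrically about the midrib (default 20°) — bending wraps the major
axis onto a circular arc and preserves area, perimeter, length and width
exactly, so every leaf carries analytic truth: s = πab, c = 4aE(1−b²/a²),
l = 2a, w = 2b. Gaussian vertex jitter (0.02 mm) stands in for scanner
noise and gives the plant a realistic, non-zero ς and ρ for the adaptive
thresholds to latch onto.

Default size variation is CV = 0.05 with a ±5 % independent shape factor
on the minor axis: fully developed leaves on a single plant are close in
size, and the acceptance band itself tolerates at most +25 % area
deviation, so a "typical" population is necessarily tight. Newborn leaves
are generated at 13–22 % of the mean linear size with a strong curl and
flagged non-typical in the ledger.

Occlusion is placed, not painted: leaves sit on a golden-angle spiral
with level-dependent vertical spacing (25/15/8/5 mm for
none/little/medium/heavy), and the placement radius is bisected until the
mean fraction of a leaf's projected area covered by higher leaves hits
the level target (0 / 0.05 / 0.15 / 0.30; small plants that cannot reach
a high mean exactly accept the closest placement within a quarter of the
target, since the topmost leaves are never covered). Scan shadowing then
removes, as one contiguous hole, the faces of a leaf covered by another
leaf less than 25 mm above it — a hand-held scanner recovers surfaces
under wider gaps by viewing them from the side. The optional
`dropout_fraction` deletes further faces uniformly. The ledger records
per-leaf face/vertex sets, analytic traits, newborn flags and the lost
face fraction; a typical leaf losing more than 10 % of its faces counts
as badly scanned (the N₂ in the accuracy ratios).

What the generator does not emulate: petiole/leaf junctions sharing mesh
vertices (stems touch but are not welded, so occlusion never *merges*
clusters topologically), leaf-surface texture and venation relief,
non-elliptical outlines, and registration artefacts of real scans.
Passing tests therefore demonstrate the pipeline's behaviour under
controlled geometric occlusion and data loss, not under every failure
mode of real scanner data.

## Accuracy statistics

R_scan = 100·N₂/N₁, R_seg1 = 100·N₃/N₂, R_seg2 = 100·N₃/N₁, reported to
two decimals, half-up. Group averages are means of the *unrounded*
per-plant ratios, then rounded — the convention that reproduces the
bundled survey's printed group rows exactly. EF = 1 − SSE/SST (1 perfect,
0 mean predictor, negative worse than the mean; undefined for constant
observations), RMSE in trait units, MAPE in percent against the manual
values. When a synthetic population is deliberately near-uniform
(CV 0.05), SST is small and EF is a harsh summary even for sub-percent
errors; MAPE is the informative figure there.

Matching segmentation output to ledger truth: a typical cluster matches a
ledger leaf when ≥ 90 % of its vertices belong to that leaf and it covers
≥ 50 % of the leaf's vertices; recall is matched typical leaves over N₁.

## Problem sizes and determinism

The shipped tests and the acceptance script run the full pipeline on
scenes of 6–8 leaves at 1.0–1.2 mm mesh resolution (≈ 15–30 k vertices
per scene), five seeded replicates per occlusion level — sizes chosen so
the whole suite exercises every stage, including the 30-level worst case,
in a few minutes on one CPU. Everything downstream of scene generation is
deterministic: region growing is seeded by minimum curvature with index
tie-breaks, RANSAC uses an explicit generator seed, and identical inputs
and configuration produce byte-identical outputs.

## Known limitations

* Graph-plus-tightening geodesics assume near-developable leaf surfaces;
  strongly crumpled leaves would need exact polyhedral geodesics.
* The tightening flow can shortcut across holes left by scan shadowing,
  slightly underestimating length on damaged leaves (which the detection
  band usually rejects anyway).
* Long, banding leaf morphologies (grasses, cereals) violate the
  elliptical length/width construction and are out of scope.
* The F-band's concentration on area (above) means a plant whose mature
  leaves genuinely span more than ±25 % in area will see its largest
  leaves classified as non-typical; that is the method's definition of
  typicality, not a bug, but it bounds the usable size spread.
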