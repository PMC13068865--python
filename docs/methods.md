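# Methods

This note records the model, conventions, parameter semantics, and the
deliberate design choices behind msiseg, at the level a maintainer or
reviewer needs to interpret its numbers.

## The Medical Similarity Index

### Model

The MSI evaluates a *test* contour T against a *reference* contour R, both
discrete ordered boundary-pixel sequences of single structures on a 2D
slice. The computation is:

1. **Center-of-mass correction.** T is translated by (COM(R) − COM(T)),
   where COM is the unweighted mean of the *filled mask's* pixel coordinates
   (the area centroid, not the boundary centroid — a boundary centroid would
   be biased by sampling density). After correction the metric is exactly
   invariant to translations of the test mask; this is intended: placement
   offsets are handled by the pairing stage and should not dilute the shape
   comparison.

2. **Bidirectional local distance (BLD).** For each test point *t*:
   forward(*t*) = min over reference points of the Euclidean distance; each
   reference point claims its nearest test point (distance ties go to the
   lower test index); backward(*t*) = the maximum distance over reference
   points claiming *t* (undefined if none do); BLD(*t*) =
   max(forward, backward), falling back to forward alone where backward is
   undefined. The backward term is what distinguishes the BLD from a plain
   directed nearest-neighbor distance: a test contour that ignores a whole
   lobe of the reference still pays for it through the points the ignored
   reference stretch claims.

3. **Direction.** A corrected test point is *inward* if it lies within the
   filled reference mask under the nearest-pixel rule (coordinates rounded
   half-up), else *outward*. Points exactly on the boundary count as inward;
   at zero distance the choice is score-neutral, so it is pinned purely for
   determinism. Out-of-bounds points are outward.

4. **Per-point similarity.** The default weighting is exponential decay
   s = exp(−ℓ·d/τ), with level ℓ = `il` (inward) or `ol` (outward) and decay
   scale τ = `distance_scale`. Properties that any registered weighting must
   preserve: s = 1 iff d = 0 or ℓ = 0, strictly decreasing in d and in ℓ
   otherwise, range (0, 1]. The exponential was chosen for its saturating
   response — successive increases of a level produce diminishing score
   drops, which matches how the clinical severity of an already-bad contour
   saturates — and it makes the concentric-circle case analytic
   (MSI = exp(−ℓ·Δr/τ)), which the test suite exploits. The weighting sits
   behind a registry (`msi.register_weighting`) so an alternative form can
   be swapped in without touching callers; a `reciprocal` variant
   1/(1 + ℓ·d/τ) ships as a second instance.

5. **Aggregation.** Contour MSI = arithmetic mean of per-point similarities
   (the mean of similarities, not a similarity of the mean distance — the
   two differ for any nonlinear weighting, and the per-point form keeps the
   per-point trace meaningful). Slice = median over its contour values
   (robust to one bad small structure); patient = mean over defined slice
   values. Slices flagged by pairing are excluded from the patient aggregate
   by default (`include_flagged` reverses this); their greedy pairing is
   still evaluated and reported for review.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `il` | 1 | — | penalty multiplier for inward (under-segmentation) deviations; 0 disables |
| `ol` | 1 | — | penalty multiplier for outward (over-segmentation) deviations; 0 disables |
| `distance_scale` (τ) | 5 | px (or mm) | distance at which an ℓ = 1 deviation decays to 1/e |
| `units` | px | — | px, or mm via the header's in-plane spacing |
| `weighting` | exponential | — | registry key of the per-point similarity |

`il`/`ol` are continuous non-negative multipliers; the values {1, 5, 10}
used in examples are instances, not an enumeration. MSI distances default to
px (matching APL's px reporting); the Hausdorff family always reports mm.

## Geometric conventions (pinned for reproducibility)

* Coordinates are 0-based `(row, col)`; the slice axis defaults to the last
  array axis (axial). Loaded NIfTI volumes are first reoriented to the
  closest canonical orientation; oblique affines are thereby approximated by
  their nearest axis-aligned interpretation.
* Connected components use 8-connectivity, sorted by descending area, ties
  by topmost-leftmost pixel.
* Contours are outer boundary pixels traced by Moore neighbor following
  with Jacob's stopping criterion, clockwise in image coordinates; holes
  are ignored. Masks of one or two pixels yield open, `degenerate`-flagged
  contours and are never split.
* Hull ratio = pixel count of the rasterized convex hull / mask pixel
  count. Rasterizing the hull (rather than taking the polygon area of the
  boundary pixel centers) keeps the ratio ≥ 1 with equality for filled
  convex rectangles. Line-like masks are defined to have ratio 1.

## Concave-mask splitting

Touching structures appear as one connected component. A component is a
splitting candidate when its area ≥ `min_area_px` (default 50 px — small
fragments produce unstable hulls and are better left to the ambiguity flag)
and its hull ratio exceeds `hull_ratio_threshold` (default 1.2). The two
convexity defects of greatest perpendicular depth — one defect per
hull-vertex gap, anchored at the middle of the maximal-depth run so that
flat necks are cut across rather than along — define a straight cut,
rasterized `cut_width_px` (default 1) thick. Components are re-extracted and
processed recursively up to `max_iterations` (default 3) levels. A candidate
with fewer than two defects, or whose cut fails to disconnect it, is
returned unchanged with a `cannot-split` flag. Splitting applies to both
reference and test masks by default, each side independently switchable.

Removed cut pixels are the only pixels lost: outputs are disjoint, their
union plus the cut equals the input, and re-running the splitter on its own
output is a no-op.

## Pairing

Each reference component is assigned its Euclidean-nearest test COM;
assignments are made greedily in ascending distance (ties by lower reference
index), each test used at most once. Distances are computed on uncorrected
pixel positions — pairing must see absolute placement; COM correction
happens only inside the MSI. The slice is flagged `ambiguous` when counts
differ, when one test COM is the nearest of two references, or when one side
is empty (missed/spurious structure). Greedy matching rather than optimal
bipartite assignment is deliberate: it is the transparent baseline
clinicians can audit, and the flag path exists precisely because no
automatic rule resolves every configuration. Optimal matching is a natural
extension hook.

## Traditional metrics

* Dice and Jaccard on pixel masks; both-empty pairs score 1.0 and are
  flagged (`both-empty`); one-empty pairs score 0 with NaN distances.
* Surface distances are nearest-neighbor distances between boundary-pixel
  sets, scaled to mm by the in-plane spacing. Hausdorff = max over both
  directions; average Hausdorff = mean of the two directed means; HD95 =
  max of the two directed 95th percentiles (linear interpolation). The
  max-of-directed combination for HD95 is the dominant convention but not
  the only one; it is recorded in the report metadata.
* Surface Dice = fraction of pooled boundary points (both directions)
  within the tolerance (default 3 mm, the common prostate setting).
* APL counts reference boundary pixels farther than `apl_tol_px` (default
  0) from the test boundary, in px — a proxy for the contour length a
  clinician would redraw. It is the one directional metric (reference-
  relative) by definition.
* All implementations are deterministic, with no point subsampling; contour
  point counts on single 2D structures stay small enough for dense distance
  matrices.

## Synthetic fixtures

The generator produces what the evaluation stages need to be tested against
ground truth, not realistic anatomy: disks, ellipses, polygons, and
dumbbells (two disks joined by a bar — the canonical touching-structures
case, hull ratio > 1.2). Perturbation modes carry their deviation direction
as a guarantee: `shift` is a pure translation; `erode`/`dent_in` produce
subsets of the original (all deviations inward); `dilate`/`bulge_out`
supersets (all outward); `merge_neighbor` attaches a touching disk. All
generators are pure functions of (spec, seed).

What this does *not* emulate: irregular organic boundaries, partial-volume
effects at mask edges, inter-slice inconsistency, or errors that mix
directions unpredictably. Passing tests demonstrate that the machinery
computes what it claims on shapes whose truth is known analytically; they do
not certify behavior on clinical contour quality, which is what the flag
log and per-point traces are for. Rasterization tolerances used throughout
the tests: 1 px for distances, 5 % for areas at radii ≥ 10 px.

## Numerical notes

* BLD ties (a reference point equidistant from two test points) resolve to
  the lower test index; the brute-force oracle in the test suite encodes the
  same rule, and equality is asserted exactly, not approximately.
* Fractional coordinates round half-up (`floor(x + 0.5)`), avoiding the
  round-half-even surprises of `np.round`.
* COM correction with integer masks is exact to the last ulp of a single
  division, so translation invariance holds to < 1e−12 rather than exactly;
  the tests assert that bound.
* Reports contain no timestamps; two runs on identical inputs produce
  byte-identical CSV/JSON outputs.

## Problem sizes

The test suite and the acceptance script run on 64–96 px grids with up to
four structures per slice and six slices per volume — large enough that
rasterized circles track their analytic geometry within the stated
tolerances, and representative of single-structure pelvic MR slices after
cropping. The full suite completes in a few seconds.

## Known limitations

* Strictly 2D: no 3D BLD or volumetric Hausdorff; the slice axis must be a
  stacking axis of the array.
* Holes in masks are ignored (outer boundary only); no hole-aware
  evaluation.
* No resampling or registration: reference and test must share grid,
  spacing, and orientation.
* The COM correction removes *all* translation signal; if placement error
  itself is clinically relevant, read it from the pairing distances or the
  Hausdorff panel, not the MSI.
* Greedy pairing can mis-assign in adversarial configurations; such slices
  are meant to be caught by the ambiguity flag, not silently scored.
* A 1-px cut cannot always disconnect genuinely diagonal necks; such masks
  come back flagged `cannot-split` (widening `cut_width_px` usually
  resolves it).
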