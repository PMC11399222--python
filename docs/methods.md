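# Methods

## Overview

`carpalkit` turns per-bone wrist segmentations into carpal-instability
measurements in four stages: (1) calibrated sub-pixel contour
extraction from label masks; (2) statistical shape-model fitting that
locates the articular facet surfaces on each contour; (3) geometric
measurement (SL distance, SL/CL angles) with threshold classification;
(4) carpal-arc construction and interruption detection against a
point-distribution-model (PDM) reconstruction of the hypothetical
normal arcs. A synthetic wrist generator supplies training fixtures and
evaluation cohorts with exact ground truth.

Coordinates are image-convention throughout (x right, y down, origin at
the top-left pixel centre); everything after ingestion is in
millimetres, and "proximal" is larger y on AP/PA canvases.

## Contour extraction

Label masks are read with their JSON sidecar; a missing pixel spacing is
fatal (measurements are metric), while missing bones only disable the
measurements that need them. Boundaries are extracted by marching
squares at the 0.5 iso-level of the binary mask, giving sub-pixel
contours whose shoelace area tracks the pixel count within 2% for blobs
larger than ~30 px. A mask that is empty or has several connected
components raises a segmentation error, mirroring how unusable automatic
segmentations are excluded upstream.

## Shape model and facet transfer

Each bone has a PDM: generalized Procrustes alignment (similarity
transforms, iteratively re-estimated mean with unit centroid size)
followed by PCA on the aligned landmark configurations. Three numerical
choices matter:

* **Metric model frame.** The model frame is rescaled so the mean shape
  has the average training centroid size; model-frame distances,
  residual scales and z-scores are therefore in millimetres of an
  average-sized wrist.
* **Tangent-space projection.** Each aligned shape is rescaled onto the
  hyperplane tangent to the consensus. Without this, the PCA mean
  (average of aligned shapes) has a slightly smaller centroid size than
  the alignment target, and training shapes fall marginally outside the
  mode subspace; with it, project-then-reconstruct at full variance is
  the identity on training shapes to machine precision.
* **Mode count and clamping.** The smallest number of modes reaching the
  variance target (default 0.95) is kept, capped at min(2n−4, m−1); at a
  variance target of exactly 1.0 every nonzero mode is kept.
  Reconstruction clamps coefficients to ±3√eigenvalue, the standard
  plausibility constraint that keeps reconstructions "normal".

Training shapes come landmarked: the generator's template vertices are
corresponded by construction and facet boundaries are exact landmark
indices, identical across the cohort (facet ranges may wrap past the
contour seam). Per-landmark residual scales are the RMS of the training
reconstruction residual magnitudes — RMS about zero rather than SD about
the mean, since residual magnitudes are non-negative deviations whose
null value is zero — floored at max(0.05 mm, observed) to prevent
infinite z-scores.

**Fitting a new contour** initialises correspondence with a cyclic
start-index search: the mean shape's per-landmark arc-length fractions
are sampled from the contour at every cyclic offset and both traversal
orientations, keeping the offset with the smallest Procrustes distance
(ties → lowest offset). Iterated closest-point refinement then
alternates clamped model projection with continuous projection of the
reconstruction onto the contour polyline, resolving correspondence below
the landmark spacing. The returned landmarks are the *boundary
projections*, not the model reconstruction: the model supplies
correspondence and facet labels, the observed contour supplies the
geometry. This keeps observation noise in the measured shapes — which is
what makes downstream z-scores honestly calibrated — while the
reconstruction-to-boundary residual is reported as fit quality.

## Measurements and thresholds

* SL distance: Euclidean distance between the arc-length mid-points of
  the facing scaphoid–lunate facets (the mid-point chord, not a
  facet-normal distance), AP/PA views only.
* Axes: capitate = mid-points of its lunate and metacarpal-III facets;
  lunate mid-plane = mid-points of its radius and capitate facets;
  scaphoid long axis = principal axis of the lateral contour (ambiguous
  below a 1.05 eigenvalue ratio, which raises). All axes are
  canonically oriented distally (negative image-y, ties toward +x);
  angles between two such axes lie in [0, 180). The distal-orientation
  rule is exact for axis tilts below 90°, so cohort distributions keep
  SL angles in [25°, 80°] although the generator accepts up to 120°.
* Classification: abnormal means strictly *exceeding* the reference
  range — SL distance > 3.0 mm neutral / > 3.7 mm ulnar-deviated
  (clenched-fist uses the neutral threshold, logged as an assumption),
  SL angle outside [30°, 60°], CL angle > 30°; boundary values are
  normal. The pediatric SL table (ages ≤ 14) ships empty: users must
  supply age-band limits from the pediatric reference literature, and a
  pediatric age without an entry is unclassifiable rather than silently
  classified with adult thresholds.

## Carpal arcs and interruption detection

The three arcs are built on the neutral AP/PA view only: proximal and
middle arcs concatenate the proximal/distal facets of scaphoid → lunate
→ triquetrum, the distal arc the proximal facets of capitate → hamate,
each oriented radial→ulnar (by increasing x; flipped wrists should be
mirrored upstream) and resampled to 100 points.

One PDM per arc is trained on non-interrupted wrists **measured through
the full pipeline** (masks → contours → fits → arcs), not on noise-free
truth geometry, so the residual scales include measurement noise and
held-out normal wrists score near z = 1. The training set includes
widened-but-aligned wrists; pure arc lengthening is therefore inside the
mode subspace and is not reported as an interruption.

Assessment aligns the observed arc into the model frame, projects with
±3σ clamping, and computes per-point z = ‖aligned − reconstruction‖ /
residual scale in the pose-normalised frame (the disruption score is
thus invariant to global similarity transforms), while displacement
vectors are mapped back to the image frame for display. The
**disruption score** is the fraction of all available arc points with
z ≥ z₍crit₎ = 2.0 — a percentage-valued, localisable, monotone summary —
detected at an operating threshold of 0.11. Markers are the contiguous
runs of exceeding points; the heat map renders the 100 points per arc
colour-coded by z with displacement-vector tails on the original image
size.

## Synthetic wrist generator

The generator is the package's study-condition definition, not a
photorealistic simulator. The AP/PA carpus lies on concentric circular
arcs around a common centre (proximal row annulus 23–34 mm, distal row
6.5–19 mm, 70 mm canvas), each bone an annulus sector with straight cut
side faces; the two faces bounding the SL joint are parallel segments
separated by exactly the requested gap, so the facet-mid-point distance
equals `sl_gap_mm` analytically. The lateral view stacks radius, lunate,
capitate (rounded head articulating about the capitolunate pivot, tilted
by the CL angle) and metacarpal base, plus an elliptical scaphoid whose
major axis realises the SL angle. Interruption is a proximal translation
of the capitate (threshold 1 mm), producing a distal-arc step-off;
infeasible parameter combinations (overlapping or self-intersecting
bones) raise rather than silently clip.

Default cohort conditions: SL gap U(1.2, 2.8) mm for normals and
U(3.5, 5.0) mm for widened cases, SL angle U(35°, 60°), CL angle
U(2°, 25°), patient scale U(0.92, 1.08), rotation U(−8°, 8°),
interrupted subluxation 3 mm, and contour jitter of 0.1 mm — a smooth
random displacement field (random Fourier features, ~2 mm correlation
length) emulating spatially correlated segmentation error; its gradient
is far below 1, so the perturbation cannot self-intersect contours.
Rasterisation fills a pixel when its centre lies inside the polygon
(pixel (i, j) centred at (j, i)·spacing); ground truth is exact at the
contour level before rasterisation, and the SL gap and subluxation are
applied in absolute millimetres regardless of patient scale.

What the generator does **not** emulate: real anatomical shape
variation (bones are one template family), projection effects,
overlapping bones in the lateral projection, X-ray physics, or the
label conventions of any particular segmentation model. Passing tests
therefore demonstrate the correctness and internal calibration of the
measurement machinery, not clinical accuracy; errors on clinical data
are expected to be dominated by segmentation and anatomic variability
that synthetic cohorts do not contain.

## Evaluation statistics

Differences are prediction − truth; limits of agreement are
bias ± 1.96·SD (sample SD, n−1). Arc agreement uses the *discrete*
Fréchet distance (dynamic programming over monotone couplings) since
arcs are fixed-size point sequences. AUC is the probability of correct
ordering with half credit for ties; the operating threshold is the
observed score maximising Youden's J (ties → lowest threshold).
Bootstrap CIs are 2.5/97.5 percentiles of 1000 stratified resamples
(strata: 1 mm bins for distances, 10° bins for angles, class labels for
detections); the percentile method is used rather than BCa. The paired
permutation test sign-flips the paired differences, enumerating all 2ⁿ
patterns exactly when that is no more work than the requested
iterations and otherwise using random flips with +1 smoothing so p
never reaches 0. The DeLong test uses placement-value covariances with
a two-sided normal p on the AUC difference. p < 0.05 two-sided is
considered significant.

## Problem sizes

Test and acceptance cohorts are sized for a single CPU: 30 training
normals, 50-case recovery cohorts at 0.1 mm/px, 100-case detection
cohorts at 0.2 mm/px, 1000 bootstrap iterations, 500-replicate coverage
checks. These sizes give Monte-Carlo error well inside every asserted
tolerance.

## Known limitations

* Facet-label transfer is defined up to the symmetry of a bone's
  outline; for the 180°-symmetric lateral templates a fit may label the
  distal face as proximal, which the canonical distal orientation of
  axes absorbs. Real bone outlines are asymmetric enough that this is a
  template artefact.
* The arc disruption score and z-score normalisation are this package's
  declared definitions of an "overall disruption score"; the 0.11
  operating threshold transfers in spirit from clinical practice and
  should be re-selected (Youden) for any new data distribution.
* The pipeline assumes right-wrist PA orientation (radial = smaller x);
  left wrists must be mirrored before measurement.
* Pediatric SL thresholds are not bundled; the angles use adult
  thresholds at all ages.
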