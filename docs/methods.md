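# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `stalksect`. All lengths are millimetres (via the
user-supplied mm/pixel calibration), areas mm², counts dimensionless.

## Section segmentation

The stalk is assumed to be the single dominant bright connected region
of a darker background. Segmentation is a fixed sequence: intensity
threshold (Otsu by default; a fixed global threshold is available for
reproducible overrides), morphological closing with a disk structuring
element (default radius 3 px), selection of the largest connected
component above `min_section_area_px` (default 5000 px), and binary hole
filling, so dark pith lacunae and vessel lumina belong to the section.
If a second component reaches 90% of the largest's area the image is
flagged as ambiguous (possible multi-stalk frame) and the largest is
kept. Multi-stalk separation is out of scope.

Section geometry is computed from the outer contour polygon (marching
squares at level 0.5, vertices at pixel centers):

* **SA** — shoelace polygon area.
* **PAD, AAD** — full major/minor axes of the moment-equivalent ellipse,
  i.e. `4·sqrt(eigenvalues)` of the polygon's normalized central
  second-moment matrix (closed-form polygon moment formulas). Moment
  axes were chosen over Feret diameters because they are robust to
  boundary noise; for a true ellipse they recover 2a and 2b exactly.
  Caveat: for strongly non-elliptical elongated shapes the moment major
  axis can exceed the enclosing-circle diameter by up to 2/√3; maize
  sections are close to elliptical, where PAD ≤ 2·CCR holds.
* **CCR** — minimum enclosing circle radius of the contour.
* **AR** — PAD/AAD, always ≥ 1.

## Epidermis ring

The epidermis is the bright outermost band. Radial intensity profiling
is realized by shell peeling on the Euclidean distance transform (EDT)
of the section mask: shell k is the set of pixels with depth in
(k−1, k]. The inner boundary is placed at the first shell whose mean
intensity falls below `epidermis_drop_fraction` (default 0.7) of the
outermost shell's mean; if no drop-off exists within 60 px the thickness
clamps to 1 px with a warning. Mean thickness is averaged over ~256
outer-boundary samples as distance to the nearest inner-boundary vertex.
No field reference value exists for this quantity, so only phantom
recovery (within 10%) is asserted.

## Concentric layers

Layers are level sets of the EDT — inward offsets of the actual
boundary, not scaled copies of the outer contour — because offsets
remain concentric and well-behaved for irregular, non-star-shaped
sections. Two schemes:

* **equal_area** (default, n = 4; the scheme the per-layer traits are
  defined on): offset depths are the k/n quantiles of the in-mask EDT
  values, which makes each band's pixel-count area equal to SA/n up to
  the granularity of tied depth values (measured deviation < 0.03% on
  phantoms, comfortably within the 1% contract).
* **equidistant**: offsets equally spaced between the boundary and the
  deepest interior point (the maximal-inscribed-disk center, which by
  construction always lies in the innermost band).

Labels run 1 (peripheral) to n (central). The epidermis band is part of
layer 1, matching the anatomical reading of the rind as the outermost
layer. A band narrower than 1 px raises a resolution error.

## Bundle detection and the three-step refinement

Candidates are bright connected components strictly inside the epidermis
inner boundary (components touching the image frame are discarded),
after a 1-px binary opening. Two threshold modes: `fixed` (global
constant) and `adaptive` (local mean over a `adaptive_window_px` window,
default 51 px, minus an offset, default −10, i.e. a pixel must exceed
its local mean by 10 counts). Before computing local means the exterior
is filled with the interior's median intensity; otherwise the dark
background depresses thresholds near the boundary and produces a
spurious ring of candidates.

Each candidate then passes three steps:

1. **Validation.** Keep a candidate iff `area ≥ A_min(d)` and
   `solidity ≥ S_min(d)`, where d ∈ [0, 1] is the candidate centroid's
   distance from the section centroid normalized by the boundary
   distance along the same ray, and both thresholds interpolate linearly
   between center (d = 0) and periphery (d = 1) values. Defaults
   `a_center_px = 80, a_periph_px = 30, s_center = 0.5, s_periph = 0.4`:
   periphery-laxer area control prevents the small, densely packed rind
   bundles from being deleted, while the stricter center thresholds
   reject parenchyma speckle. Solidity (area over convex-hull area) is
   the shape criterion because it composes naturally with step 2.
2. **Convex hull** of the raw contour (qhull), counter-clockwise
   vertices. The hull repairs ragged threshold boundaries; it never
   decreases area.
3. **Closed spline.** The hull is resampled at K = 12 (`spline_nodes`)
   equal-arc-length control points and interpolated by a periodic cubic
   (`CubicSpline(bc_type="periodic")`), sampled at 16·K points. The
   sampled polygon is the bundle's final contour: its shoelace area and
   centroid are the reported `area_mm2` and `centroid`, and the control
   points are the programmatic handle for shape editing (re-evaluation
   after moving nodes is exposed; no GUI is built). Raw and hull areas
   are also retained and serialized. Note that an interpolating cubic
   through very few nodes *overshoots* at sharp corners (through the 4
   corners of a square it bulges out to nearly the circumscribed
   circle); on the near-elliptical hulls of real bundles with K = 12 the
   spline area stays within a few percent of the hull area.

Bundle uids are assigned in raster-scan order of centroids; the owner
layer is the layer label at the centroid pixel (a centroid exactly on a
boundary pixel therefore takes that pixel's label, i.e. the outer band —
deterministic tie-break); `size_class` is a purely descriptive per-slice
area tercile.

## The 21 traits

Four section traits (PAD, AAD, CCR, SA), five counts (VB and the
per-layer PVB, CVB-2, CVB-3, CVB-4), four per-layer areas (PA, CA-2..4),
four per-layer area ratios (PAR, CAR-2..4), MA = TA/VB, TA, Rsection =
TA/SA, and AR. Conventions that the source material leaves open:

* **Ratio denominators.** PAR and CAR-k divide each layer's bundle area
  by *that layer's own area* (≈ SA/4 under equal-area layering), not by
  SA. This keeps the four ratios directly comparable across layers but
  makes each roughly 4× larger than an SA-denominator convention —
  users comparing to other tools should check which convention those
  use.
* A bundle belongs wholly to the layer containing its centroid; areas
  are not split across layer boundaries.
* Bundle area is the spline-polygon (outer-contour) area; interior
  lacunae do not reduce it.

The trait scheme is four-layer-specific; `compute_traits` rejects other
layer counts. Additivity (VB and TA decompositions) holds exactly by
construction.

## Synthetic phantoms

A phantom renders: elliptical section (default semi-axes 280 × 230 px),
epidermis band of uniform depth (12 px) at intensity 220, parenchyma 90,
background 20, bundle disks at 180, Gaussian noise (sd 3) added then
clipped to [0, 255]. 70 rind bundles (radius 4–6 px) are placed with
centers in the peripheral equal-area band and 50 pith bundles (radius
7–11 px) in the central bands, by rejection sampling with a 3-px minimum
gap between disks and from the epidermis (at most 10⁴ attempts per
bundle, else a packing error naming the constraint). The intensity set
is chosen so Otsu separates section from background and local-mean
thresholding separates bundles from parenchyma. All randomness flows
from one seeded generator per call.

Ground truth records each bundle's center, radius, pixel-count area, and
owner layer (computed with the same layer algorithm on the clean mask),
plus the implied 21-trait vector. A per-bundle flag marks centroids at
least 2 px from every layer offset, for which layer recovery is checked
exactly.

`generate_cohort` simulates a two-variety study: per-sample phantoms
from two specs, full pipeline on each, and a bending-strength column
generated as a stated linear function of the *measured* traits plus
Gaussian noise, enabling regression-recovery experiments with a known
generative model. Each cohort sample's section semi-axes are jittered
independently by ±8% to emulate plant-to-plant size variability (with
fixed axes the section traits would be constant columns and the
statistics stage degenerate); the batch `phantom` CLI command applies
the same jitter across a batch. What phantoms do **not** emulate:
CT physics (beam hardening, ring artifacts, partial-volume blur),
non-elliptical section outlines, anisotropic or lobed bundle shapes,
intensity gradients across the section. Passing recovery tests
therefore demonstrates correctness of the geometry and bookkeeping under
realistic contrast and packing, not robustness to scanner artifacts.

## Statistics

* **PCA** on the correlation matrix (columns standardized to unit
  variance; constant columns dropped with a warning), via SVD of the
  standardized matrix; explained-variance fractions sum to 1.
* **Correlation screen**: Pearson r of each trait against BS with
  two-sided p from the t distribution (n − 2 df); significance at
  p < alpha (default 0.05), no multiple-testing correction by default
  (a Benjamini–Hochberg column is available off by default).
* **Stepwise AIC**: bidirectional search starting from the full
  candidate model; at each step the single add/drop most reducing
  `AIC = n·log(RSS/n) + 2k` (k = estimated coefficients including the
  intercept — additive constants cancel in comparisons) is taken until a
  local minimum. Perfect collinearity in the candidate design raises an
  error naming the aliased set. An exhaustive 2^k subset search is
  provided as a reference; on the simulated cohorts used in the tests
  the stepwise optimum coincides with the exhaustive optimum. Like R's
  `step`, AIC deliberately tolerates a ~16% per-variable chance of
  retaining a spurious predictor; tests assert true-model content and
  oracle equivalence rather than exact minimal-model selection.
* **Diagnostics**: per-sample residual, leverage (hat diagonal; sums to
  the parameter count), and Cook's distance, flagging samples above 4/n.
  Row exclusion for poor-quality samples is explicitly the user's
  decision; the tool never drops rows silently.

OLS fitting, influence measures, and p-values come from statsmodels;
the stepwise search and the AIC convention are implemented here.

## Serialization and determinism

Per-slice results are versioned JSON (schema_version 1): contours as
vertex lists, traits as a named map, spline control points (the sampled
polygon is re-evaluated deterministically on load), and the SHA-256
digest of the full parameter set for provenance. Rasters are not stored;
everything downstream of segmentation is carried by contours and
scalars. JSON floats round-trip exactly (shortest-repr encoding), so
save/load is the identity on contours and traits. Batch analysis treats
each image as an independent task merged in source_id order, so trait
tables are byte-identical for any worker count.

## Problem sizes used in the self-checks

The automated checks run 20 default phantoms (~600 × 500 px, ~120
bundles each) for recovery statistics, simulated cohorts of 8–12 slices
for regression recovery, 1000 null draws for the screen's type-I error,
and all 256 subsets of 8 candidates for the stepwise reference — sizes
at which every expected value is computable exactly or by a stated
oracle.

## Known limitations

* Single stalk per image; no touching-sample separation.
* The epidermis drop-off rule assumes a ring brighter than the tissue
  immediately beneath it; stains or acquisition settings that invert
  this contrast require a custom `epidermis_drop_fraction`.
* Bundle areas are outer-contour areas; vessel-level (lumen/phloem/
  sheath) phenotyping is not attempted.
* Layer decomposition offers one geometry (EDT offsets); anatomically
  adaptive layering (e.g. detecting the true rind–pith interface) is a
  non-goal.
* The validation thresholds are exposed in config and calibrated on
  phantoms; real scans with different contrast may need retuning.
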