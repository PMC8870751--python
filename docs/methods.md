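# Methods

This note documents the models, discretizations and design choices behind
`kneemorph`: what each stage computes, which parameters matter, what the
synthetic cohort does and does not emulate, and the numerical conventions.

## 1. Problem and workflow

Osteoarthritic degeneration of knee cartilage manifests as thinning,
surface roughening and, in advanced disease, full-thickness defects
("holes"). The package implements a 3D assessment workflow over
segmented knee compartments — three bones (femur, tibia, patella) and
four cartilages (femoral, lateral tibial, medial tibial, patellar):

1. **Densitometry** — per-compartment radiodensity statistics on the CT
   voxel grid (Hounsfield units), with cartilage voxels isolated by an
   inclusive 0–300 HU window, and bone density mapped to bone mineral
   density (BMD, g/cm³) by a phantom-calibrated affine formula.
2. **Mesh morphometry** — per-element wall thickness and discrete
   Gaussian curvature over triangulated cartilage shells; detection and
   ellipse-based grading of through-holes.
3. **Feature statistics** — area-normalized per-element summaries and
   tail fractions (the W/C percent statistics).
4. **Group statistics** — Shapiro–Wilk screen, tie-corrected
   Kruskal–Wallis omnibus over the three groups (degenerative D,
   traumatic T, control C), Dunn's rank post hoc on (C–D, D–T, T–C).
5. **Classification** — decision tree, random forest and gradient
   boosting over five feature selections under stratified 5-fold
   cross-validation, with random-forest impurity importances.

Because no patient imaging is distributed, a first-class synthetic
cohort generator provides geometry and voxel data with exact ground
truth; all pipeline stages operate on its output exactly as they would
on segmented scans.

## 2. Mesh morphometry

### Wall thickness

Thickness of a closed shell is measured per face: a ray is cast from the
face centroid along the inward normal, excluding the face itself and its
edge-neighbours; the thickness is the distance to the first hit. If no
hit lies within `max_thickness` (default 25 mm, generous for cartilage),
the distance to the nearest point on any non-adjacent face is used;
failing that the element is flagged invalid. The single-ray contract was
chosen because it is exactly checkable on offset surfaces (a uniform
spherical shell of thickness *t* must report *t* everywhere); commercial
mesh tools implement proprietary variants of the same surface-to-surface
idea. A cone-of-rays variant is not provided; rim and tunnel-wall faces
of open-rimmed shells report the local rim geometry rather than the
plate thickness and are simply part of the element population, as they
are in real exports (edge artifacts are visible in practice around
cartilage borders).

Ray–triangle intersection is Möller–Trumbore, evaluated against every
face (brute force, vectorized); correctness is asserted in tests against
an independently formulated per-ray oracle, so no spatial acceleration
structure is load-bearing.

### Gaussian curvature

The intrinsic curvature is discretized by the vertex angle deficit:
`K_v = (2π − Σ incident angles) / A_v`, with `A_v` the barycentric
one-third of incident face areas. Boundary vertices carry no deficit and
are invalid. Per-face values are the arithmetic mean of the face's valid
vertex values (the discretization of the "element value" is not uniquely
defined; the mean is the simplest consistent transfer). Two exact
identities anchor the implementation: the total angle deficit of any
closed mesh equals `2πχ` (Gauss–Bonnet, asserted to 1e-8 relative on
every fixture), and a sphere of radius *r* must report `1/r²`.

### Holes

On an open cartilage patch, every interior boundary loop is a
through-defect. Loops are extracted from edges incident to exactly one
face; the loop with the largest projected area is the outer rim, the
rest are holes. Each hole's vertices are projected onto their best-fit
plane (SVD principal axes) and an ellipse is fitted by stable direct
least squares, falling back to the second-moment (covariance) ellipse
when the conic fit degenerates; the hole area is `πab`. A compartment is
graded 0 (no holes), 1 (total area ≤ 20 mm², inclusive at the boundary)
or 2 (> 20 mm²). Grading is applied to the compartment's summed hole
area, matching the granularity of per-patient total-area bookkeeping;
per-hole records are also emitted.

## 3. Densitometry

- Threshold window inclusive at both ends (`lo ≤ HU ≤ hi`).
- Density statistics use the n−1 SD convention; compartment volume is
  voxel count × voxel volume.
- BMD calibration is ordinary least squares over explicit (HU, g/cm³)
  phantom pairs; the shipped default pairs {(0, 1.000), (1000, 1.800)}
  are configuration, not physics — real use must supply the scanner's
  phantom. Bone features are reported on the BMD scale, cartilage on the
  HU scale; the bone "STD" feature is the intra-subject per-voxel SD of
  the same quantity (the alternative — an inter-scan SD — is not
  computable from a single volume).
- Mask iso-surfaces use marching cubes at the 0.5 level after a 1-voxel
  Gaussian pre-smooth. The smoothing suppresses the staircase artifact
  of binary iso-surfacing, which otherwise inflates a sphere's area by
  ~9% at 0.5 mm spacing; with it the area is within 5% of analytic.
  Masks too thin to survive smoothing fall back to raw binary
  extraction (a single voxel yields the octahedral surface, area √3).

## 4. Area-normalized statistics

Raw per-element values are not comparable across meshes because element
sizes differ, so each value is weighted by its element area,
`Y_i = A_i·X_i`, and all statistics are taken over the normalized set:
mean, STD, VAR (n−1), RMS, and two tail fractions

- `W% = #{Y_i < μ − ασ} / NE` for wall thickness (excess thin mass),
- `C% = #{Y_i > μ + ασ} / NE` for curvature (excess rough mass),

with strict inequalities and `μ, σ` computed from the same individual
analysis (per subject × compartment × analysis). A cohort-pooled-μ
variant is deliberately not the default: the per-analysis convention
makes the statistic scale-free, hence invariant under uniform area
scaling (tested). The weight α is constant per (compartment, analysis)
across all subjects; defaults are 0.5 for wall on the femoral, patellar
and medial tibial compartments, 0.3 for the lateral tibial, and 5 for
curvature everywhere. `select_alpha` reproduces the weight-selection
procedure as a deterministic grid search maximizing the Kruskal–Wallis H
of the per-subject fractions across groups (ties toward smaller α).

Per subject this yields 4 compartments × 2 analyses × 6 parameters = 48
named values (`{Fem,Pat,Lat,Med}{Wall,Curv}{Mean,STD,Var,RMS,
Below/AboveSTDWeight,STDWeight}`). One casing is used consistently for
the tail-fraction suffix.

Because `W%` depends only on the standardized shape of the normalized
distribution, group separation requires *shape* differences (bimodality
from thinned patches, skew from defects), not mere location or scale
shifts — this drives the generator's design below.

## 5. Group statistics

Shapiro–Wilk (Royston approximation, n between 3 and 5000) screens each
group; a constant sample is reported non-computable. The omnibus is the
tie-corrected Kruskal–Wallis H with a χ²(k−1) p-value. Dunn's post hoc z
on the joint ranks uses the tie-corrected pooled variance
`N(N+1)/12 − Σ(t³−t)/(12(N−1))`; p-values are two-sided normal and
**unadjusted by default** (reported post hoc p-values in this workflow
convention carry no correction; Holm step-down is available by flag).
Post hoc tests run only when the omnibus p < 0.05 (configurable).

Calibration: under a half-normal null at group sizes (24, 15, 8) the
omnibus rejects at 3–7% over 2000 simulations (tested). The asymptotic
χ² p tracks a label-permutation oracle to within ~0.01 absolute at these
sizes; the residual is the χ² approximation bias, which is larger than
the Monte-Carlo noise of a 10⁵-replicate oracle — the package's test
asserts the defensible absolute tolerance (|Δp| < 0.015).

## 6. Classification

Five selections: Bone (8), Cartilage (16), B-C (24), WT-C (48 minus the
8 constant α columns minus a configurable unstable list), TOT (B-C ∪
WT-C). Hole features are never included (mostly zero, uninformative).
The unstable-feature rule drops WT-C columns whose cross-subject
coefficient of variation exceeds a threshold (default 5.0); the default
exclusion list is empty because the original exclusion set is not
recoverable without the source feature table.

Learners: decision tree (Gini, unpruned), random forest (100 trees,
unlimited depth), gradient boosting (100 rounds, learning rate 0.1,
depth 3) — the upstream analytics platform's defaults are unpublished,
so these ship as explicit configuration. Folds are stratified (k = 5 by
default, reduced with a warning when the smallest class is smaller than
k); out-of-fold predictions are pooled into one confusion matrix from
which accuracy, per-class sensitivity and one-vs-rest specificity are
computed. Importance is mean impurity decrease of a forest fitted on the
full table, normalized to percentages summing to 100.

## 7. The synthetic cohort

### What it emulates

Each compartment is a spherical-cap shell: two offset caps joined at the
rim, radius fixed per compartment (55 mm femoral, 22 mm tibial, 20 mm
patellar) and cap extent chosen to realize the subject's drawn surface
area. Caps were chosen because area, curvature (1/R²), offsets and
geodesic-circle areas are analytic, giving exact oracles for every
downstream analysis. Scalar draws (BMD per bone, HU / volume / surface
per cartilage, patella volume and surface) are Gaussian with the
published group means and SDs as moments — the intra-group distribution
shape is an assumption (only mean/SD/median are reported), and draws are
floored at small positive values to keep geometry realizable, which
biases moments negligibly at the default parameters.

Damage structure, the part that drives the morphometric statistics:

- **Through-holes**: a subject carries holes with the empirical group
  rate (8/24 for D, 1/15 for T, 0 for C); a hole-bearing subject
  realizes one of the printed per-patient rows (per-compartment count
  and total area), split across holes by a Dirichlet draw with axis
  ratios in [1, 2]. Holes are realized both as tunnels through the
  closed shell (Euler characteristic 2 − 2·holes, tested) and as
  interior boundary loops of the open patch, with exact analytic area
  πab recorded as ground truth.
- **Thinning patches**: geodesic circles of halved thickness covering a
  target area fraction (0.40 D, 0.15 T, 0.02 C). Degenerative knees in
  this cohort are end-stage (prosthesis waiting list), so extensive
  thinning is the intended phenomenology; it produces the bimodal
  thickness distributions that the W% statistic detects at α = 0.5.
- **Roughness**: smooth random undulation plus sharp crater-like bumps
  whose count scales with the group amplitude (0.12 mm D, 0.06 T,
  0.02 C), giving heavy curvature tails.

Voxel volumes are schematic: disjoint spheres/ellipsoids per compartment
sized to the drawn volumes, painted with the drawn densities (cartilage
means clipped into [0, 300] HU before noise; bone levels are the HU
pre-image of the drawn BMD under the active calibration), plus additive
Gaussian voxel noise (default SD 10 HU; no noise model is published, so
this is a plain-CT-like choice).

### What it does not emulate

Anatomical knee geometry, partial-volume and beam-hardening effects,
registration error, segmentation subjectivity, and spatial correlation
between compartments. Passing tests therefore demonstrate that the
*algorithms* recover known structure from data with the assumed
statistical shape — not that the features separate real patient groups.

### Determinism

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning; a fixed seed yields byte-identical manifests and feature
tables. Mesh jitter and roughness draw from the same stream and can be
disabled.

## 8. Numerical conventions and scale choices

- Units: millimetres, mm², mm³, HU, g/cm³ throughout.
- Vertex weld tolerance 1e-6 mm on STL import; degenerate faces
  (area ≤ 1e-10 mm²) dropped with a logged count; ray hits closer than
  1e-6 mm ignored.
- Grid step of the cap triangulation is `Rd/(6·2^refinement)` (Rd the
  geodesic cap radius); hole rims are sampled with at least 32 boundary
  points regardless of grid step, plus a guard ring that pins the rim
  into the Delaunay triangulation. A hole with semi-minor axis below
  1/40 of the grid step is rejected with the minimum refinement named.
- Default problem sizes: refinement 1 (≈2000 faces per shell) and
  0.5 mm voxels for cohort work; refinement 2+ for single-shell
  geometry oracles. These keep a full 47-subject pipeline run in the
  minutes range while leaving every oracle tolerance satisfied with
  margin; both are configuration.
- The azimuthal metric distortion of the disk→sphere exponential map is
  compensated when placing holes and patches, so requested semi-axes are
  metrically true on the sphere to first order (fitted hole areas
  recover ground truth within a few percent at default sizes).

## 9. Known limitations

- Wall thickness ignores holes (thin rims around defects are reported
  as-is); hole-aware thickness correction is out of scope.
- Curvature separation between groups is weak by construction at α = 5
  (tail fractions are near zero for all groups) — consistent with the
  phenomenon that curvature-based separation is harder than
  thickness-based separation.
- The Table-style "presence of holes (%)" summary has no defined
  denominator and is not reproduced.
- Subregion parcellation (medial/lateral condyle zones), cross-subject
  field registration, SMOTE-style rebalancing and deep models are out
  of scope.
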