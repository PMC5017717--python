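# Methods

This document describes the models, algorithms, parameters and numerical
choices implemented in `liverreg`. It states what the code computes; all
empirical numbers live in the test suite and in the output of
`scripts/acceptance.py`, not here.

## Problem setting

Percutaneous tumor ablation is guided by intra-operative CT, but the tumor
is often only visible in a pre-operative contrast-enhanced diagnostic CT
(`D`) in which liver and tumor have been segmented. The package maps those
annotations onto the intra-operative images:

* `F` — a full-liver intra-operative CT (usually non-contrast), acquired at
  the start of the intervention;
* `N` — a needle-check CT with only a few axial slices, acquired during
  needle placement, possibly shifted by patient/breathing drift relative to
  `F`.

Registration runs in two stages:

1. **Stage 1 (`stage1`)** — non-rigid registration of `D` to `F`,
   initialized by a center-of-mass alignment plus a user-supplied manual
   rotation about the table axis (`z_rotation_deg`). If the operator
   rejects the result, **refinement (`refine`)** re-runs stage 1 with a
   local rigidity penalty active around user-placed seed points.
2. **Stage 2 (`stage2`)** — rigid registration of `F` to the thin slab `N`
   (drift compensation), followed by a non-rigid registration of `D` to `N`
   initialized by the composition `T_DF ∘ T_FN` and restricted to the finer
   grid levels. A *concatenation-only* mode skips the final non-rigid step
   and uses the composition directly.

All transforms map **fixed-domain world coordinates (mm) into the moving
image** (pull-back convention); resampling an image through a transform
therefore needs no transform inversion.

## Transform model

Non-rigid transforms are cubic B-spline free-form deformations (FFD): a
regular control-point grid with spacing `h` carries displacement vectors
`mu`, and the displacement at `x` is the tensor-product cubic B-spline
interpolation of the 4×4×4 surrounding control points. Analytic first and
second spatial derivatives come from the B-spline basis derivatives.
Key properties used by the tests: partition of unity (constant coefficients
reproduce a global translation exactly) and linear precision via
`embed_affine` (an affine map embedded into the FFD reproduces it to
machine precision inside the supported domain).

Grid refinement between resolution levels uses exact dyadic cubic B-spline
subdivision when the spacing halves (the default 80→40→20→10 mm schedule);
a sample-and-prefilter path covers non-dyadic ratios (approximate, since
the coarse spline space is not nested in a non-dyadic fine space).

Outside the FFD's supported region evaluation either raises (`extrapolate
= "error"`, the default) or returns zero displacement (`"zero"`, used for
synthetic truth fields).

## Similarity metric

Negated mutual information (MI) of the joint intensity histogram, natural
logarithm, 32 bins per axis by default. Per iteration, 2000 points are
drawn uniformly from the fixed-image liver mask (fresh samples every
iteration — stochastic gradient). The fixed intensity is binned with a box
window (its marginal is constant w.r.t. the transform), the moving
intensity with a cubic B-spline Parzen window, making the histogram — and
hence MI — differentiable in the transform parameters. Moving intensities
and their gradients come from a prefiltered cubic B-spline interpolant of
the moving image (mirror boundary, exact interpolation at voxel centers),
so the analytic gradient and finite differences differentiate the same
function.

Samples mapped outside the moving volume are dropped; if more than 50 % of
samples drop, a gross-misalignment error is raised. Histogram intensity
ranges are computed inside the fixed mask and, when a `moving_mask` is
given, inside that mask: without this restriction the bins span the full
air-to-metal range (≈ 37 HU per bin at CT range) and small soft-tissue
contrasts (e.g. a 30 HU tumor) become invisible to the metric. The
pipeline passes the diagnostic liver mask dilated by 12 mm.

## Local rigidity penalty

Refinement minimizes `-MI + alpha * P_rigid`, where `P_rigid` is the
`c`-weighted mean over evaluation points of

```
c_AC * Σ (∂²T/∂x²)²  +  c_OC * Σ (JᵀJ - I)²  +  c_PC * (det J - 1)²
```

(affinity, orthonormality and properness conditions; all three vanish
exactly where the transform is locally rigid). Defaults: `c_AC = 100`,
`c_OC = 1`, `c_PC = 2`, `alpha = [0.1, 0.1, 0.1, 4.0]` per resolution
level. The coefficient field `c(x) ∈ [0, 1]` is built by dilating each
user seed with a 1 cm cube (rounded up to an odd voxel count), with an
optional smoothstep feather (default 5 mm) based on the Euclidean distance
transform. `c` lives on the moving (diagnostic) image and is evaluated at
the transformed positions; its weights are frozen when differentiating the
penalty (frozen-weight approximation), so the analytic gradient only
differentiates the rigidity conditions.

The penalty is evaluated on a regular grid with 15 mm spacing (independent
of the control-grid spacing; at the coarse 80 mm level a control-point
grid would miss centimeter-scale seeded regions entirely).

## Optimization

Robbins–Monro stochastic gradient descent with gain
`gamma_t = a / (A + t + 1)^0.602`, `A = 50`, over a fixed iteration budget
(default 500 per level; the acceptance scenarios use 100). The gain `a` is
auto-scaled per level so that the first step's largest control-point
motion equals 10 % of that level's grid spacing — calibrated on phantom
runs before the acceptance thresholds were frozen. Four resolution levels
combine image Gaussian pyramids (downsampling factors 8/4/2/1, sigma =
factor/2, clamped per axis so no axis shrinks below 4 voxels — required by
the thin needle slab) with grid refinement (80/40/20/10 mm).

The stage-2 rigid registration optimizes scaled Euler angles (characteristic
arm 100 mm) plus translation with a central finite-difference gradient of
the sampled MI (the FD gradient of the sampled cost is exact up to O(h²);
analytic rigid derivatives were judged not worth the code surface). Voxels
brighter than 1500 HU (the metal needle) are excluded from the slab's
fixed mask, with a 2-voxel dilation to cover partial-volume halos. After
the SGD levels a deterministic Powell polish on one large fixed sample set
(20 000 points) removes the residual stochastic wander; SGD steps alone
cannot anneal below roughly half a millimetre within the budget.

All randomness derives from `RegistrationConfig.seed`; repeated runs are
bit-identical.

## Evaluation and the success rule

* **DSC** — Dice overlap of the mapped diagnostic liver mask against the
  fixed-frame liver mask.
* **MSD** — symmetric mean closest surface distance (surfaces extracted as
  mask minus one-voxel erosion, 6-connected; distances via the Euclidean
  distance transform with world spacing).
* **MCD** — mean distance between paired landmarks after applying the
  estimated transform.

A registration is classified a **success** when DSC > 0.80 and, if
landmarks are available, MCD < 10 mm; otherwise it **needs refinement**
(both thresholds strict). The CLI exits with code 2 in the latter case.

## Synthetic phantom

Because clinical data is unavailable, a deformable digital phantom makes
every stage testable:

* **Diagnostic volume** — piecewise-constant HU: air −1000, soft tissue
  40, background blobs 70, liver 100 (ellipsoid with optional radial
  roughness), vessels 180 when contrast-enhanced (a random binary tree
  whose branch/midpoints double as landmarks, ≤ 15), tumor = liver − 30 HU,
  plus optional Gaussian noise.
* **Intra-operative volume** — the diagnostic anatomy under a known truth
  transform: a rigid pose change (default 30° about z plus a translation)
  composed with a smooth random breathing FFD (default 15 mm amplitude,
  50 mm grid). Fold-over (non-positive Jacobian determinant) is rejected.
  Vessels render at liver HU (non-contrast).
* **Needle slab** — a few axial slices (default 5) cut from `F` around the
  tumor's intra-operative position, under an additional small rigid drift,
  with a synthetic 3000 HU needle and optionally an extra non-rigid
  breathing-state change.

The truth transforms are returned alongside the images, so landmark and
mask errors against ground truth are exact.

### Scope and limitations

* The phantom is desk-scale (default 128×128×96 at 2×2×3 mm; the test
  scenarios use 96×96×64 at 2.5×2.5×3.5 mm) — far coarser and cleaner
  than clinical CT. Quantitative results on it do not transfer to clinical
  cohorts; the acceptance scenarios therefore test properties (recovery
  bounds, orderings, invariances), not clinical numbers.
* Breathing is modeled as a smooth random FFD, not a physiological motion
  model; sliding at the liver–rib interface is not modeled.
* The success rule's thresholds are those of the reference workflow and are
  not tuned to the phantom.
* The frozen-weight rigidity gradient is an approximation; it is exact for
  a uniform coefficient mask.
* MCD is computed from vessel-derived landmarks; with few landmarks it is
  a noisy error estimate.
* The final non-rigid D→N registration is poorly constrained in the
  through-plane direction: a 5-slice slab (≈ 17.5 mm) gives the metric
  almost no leverage on z displacements, and large through-plane drift can
  make the non-rigid refinement worse than the plain concatenation. The
  stage-2 test scenarios therefore use predominantly in-plane drift; for
  clinical-style through-plane motion the concatenation-only mode is the
  safer choice.
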