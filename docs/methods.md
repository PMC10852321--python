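# Methods

This note documents the models, numerical choices and limitations of
`surfdetect`. It is written for someone who wants to trust (or
challenge) what the tests and analysis scripts compute.

## Template surface

The template is two icosphere hemispheres (default subdivision level 4:
2,562 vertices each; radius 100 mm) placed mirror-symmetrically, so
vertex *i* on the left corresponds to vertex *i* on the right. Total
surface area is ≈ 2.5·10⁵ mm², the same order as a human cortex, so
millimetre-valued smoothing kernels (4/8/32 mm FWHM) and lesion radii
keep their physical meaning. Per-vertex area is one third of the
incident triangle areas and sums exactly to the mesh area. The two
hemispheres share no edges: smoothing, clustering and flood fill can
never cross the midline.

A real symmetric cortical template differs in ways that matter for
interpretation: cortical folding makes geodesic distances anisotropic,
vertex areas are far less uniform after registration, and lobar parcels
have characteristic shapes. None of these affect the statistical
machinery, which only consumes areas, adjacency and distances.

## Surface smoothing

Smoothing is iterative mass-conserving neighbour diffusion:
`x ← x + τ·M⁻¹(W − D)x` with unit edge weights `W`, degree `D` and
vertex-area mass `M`. Because `W − D` has zero column sums, the
area-weighted mean of any field is conserved to machine precision;
constants are fixed points; the operator is linear. The pair
(iteration count, step fraction) is calibrated once per mesh and FWHM
so that a point-source response, fitted by its second spatial moment
against graph-geodesic distance, has the requested FWHM; calibration
uses three probe vertices and one multiplicative refinement, and is
cached on the mesh. Achieved FWHM is within a few percent of the
request (7.8 mm for a requested 8 mm at level 4) — but kernels narrower
than the local edge length cannot be realised, so a 4 mm request on a
level-3 mesh (13 mm edges) degenerates to minimal smoothing. The 4 mm
post-smoothing of classifier maps is therefore only meaningful at
level 4 and above.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
not images. Each of the 19 base measures (sulcal depth, curvature,
area, volume, thickness, absolute intrinsic curvature, white/grey
contrast, and normalized T1/FLAIR intensity at six cortical depths) is

```
map = smooth population mean + covariate effects + subject intercept
      + spatially correlated vertex noise
```

* Population mean patterns and covariate-slope modulation fields are
  smooth (40 mm FWHM) random fields, fixed per cohort seed.
* Covariates: age ~ N(30, 8²) years, binary sex and scanner site,
  an intracranial-volume analog ~ N(1500, 130²) ml. Effects are linear
  per vertex (e.g. thickness: −0.004 mm/year), so the GLM's model class
  is exactly correct — deliberate, since the GLM calibration tests are
  about the z-construction, not about model misspecification.
* Between-subject variability per measure is split 30% into a global
  subject intercept and 70% into vertex noise, smoothed at 15 mm FWHM
  and restandardized. `noise_sd` scales all subject-level variability
  together, so `noise_sd = 0` makes maps deterministic.
* T1/FLAIR depth maps share a per-modality smooth latent and subject
  intercept, giving adjacent-depth correlations ≈ 0.6; T1 increases
  toward white matter, FLAIR decreases. Raw intensities are rescaled
  per subject by a two-point affine map: median mid-cortical intensity
  → 0, median 1-mm-subcortical intensity → 1 (an nFSI-style
  normalization; the exact reference formula is a documented choice).
  White/grey contrast is derived deterministically from the raw T1
  depth maps as a percent contrast,
  `100·(T1₋₁ₘₘ − T1₅₀%)/(0.5·(T1₋₁ₘₘ + T1₅₀%))`, so subcortical T1
  implants propagate into it.
* Lesions are geodesic disks (default radius 13–36 mm, matching label
  relative sizes φ ≈ 0.002–0.016 on this template) implanted on the
  *primitive* maps with the FCD-like sign profile: thickness up,
  subcortical T1 down, subcortical FLAIR up (contrast falls as a
  consequence). Effects are in control-SD units of the affected
  measure; a +4 SD implant is recovered empirically to within a few
  percent. MRI-negative subjects get the same profile scaled by
  `negative_effect_scale` (default 0.3) inside a sub-patch of one
  parcel of their hypothesis label, which is a union of 1–3
  flood-fill parcels with φ drawn inside (0.02, 0.36).
* The default cohort layout mirrors the reference clinical cohort: 94 controls, 5
  MRI-positive patients carrying 6 lesions, 27 MRI-negative patients.

What passing tests on these cohorts show: the z-construction,
standardization, AFROC accounting and null simulation are correct, and
the detectors behave sensibly under controlled effect sizes. What they
cannot show: robustness to segmentation artefacts, registration error,
non-Gaussian intensity distributions, or covariate nonlinearity — none
of which the generator emulates.

## Feature bank and standardization

Each base measure yields four features: smoothed at 8 mm, smoothed at
32 mm, their difference (difference-of-Gaussians band-pass, which has
exactly zero area-weighted mean by mass conservation), and
interhemispheric asymmetry computed on the raw map then smoothed at
8 mm (raw-first, matching the stated processing order). 19 measures →
76 features; the six subsets are `all` (76), `base8` (19), `reduced`
(6 informative measures × 4 = 24) and each without FLAIR (52/13/16).

Z-scoring is two-stage: per subject (each feature over all vertices,
hemispheres pooled) then per vertex (each cell over the control
reference). A control subject's own evaluation matrix uses the
leave-one-out reference; training matrices use the full-control
reference so one pooled training matrix can be shared (the difference
is O(1/n) per cell).

## Univariate GLM

For each measure at 8 mm smoothing, ordinary least squares of the
control maps on intercept, age, sex, site (+ ICV analog for area,
volume, thickness), per vertex. The evaluated subject becomes
`z = (y₀ − x₀ᵀβ̂)/(s·√(1 + x₀ᵀ(XᵀX)⁻¹x₀))` with `s` on n − p degrees
of freedom — a prediction residual whose leave-one-out control version
is t-distributed, treated as normal (at n ≥ 30 the SD inflation is
≈ 1%, inside the tested [0.9, 1.1] band). Zero-residual-SD vertices
get z = 0 with a warning. Controls are always scored against the other
controls only.

## Novelty detection and comparator

* Mahalanobis: minimum-covariance-determinant location/scatter
  (support fraction 0.75, configurable); score is the distance itself
  (affine-invariant, χ²ₖ-calibrated on Gaussian data).
* Isolation forest: 100 trees, subsampling size ψ = 2048 (lowered with
  a warning on smaller training sets); score is the original
  path-length-normalized anomaly score in (0, 1].
* Random forest comparator: 100 trees, √k features per split, Gini,
  leaves down to single observations; control vertices subsampled to a
  1:10 lesional:control ratio; score is the lesional-class probability.
  Strict lesion labels feed training; wide labels are evaluation-only.
* Training pools all vertices of the scheduled subjects; a subject's
  own vertices never train the model that scores it (one shared model
  for patients, one leave-one-out model per control; RFC additionally
  refits per evaluated MRI-positive subject). Training matrices above
  2·10⁶ rows are subsampled with a seeded draw. Score maps are
  post-smoothed at 4 mm FWHM; convex averaging preserves the [0, 1]
  and nonnegativity range contracts.

## AFROC evaluation

Maps are thresholded over a grid of pooled empirical quantiles
(default 512 thresholds). Half the grid covers the bulk uniformly in
quantile space; the other half is packed geometrically into the upper
tail down to the pooled maximum, because the entire FPF transition
happens where per-subject maxima cross the threshold — with uniform
quantile spacing that region collapses into a single trapezoid segment
and the AUC estimate becomes meaningless. Two-tailed maps (GLM z) are
thresholded on |z|, which merges the tails before clustering.

Suprathreshold vertices are clustered by edge connectivity; each
cluster becomes one mark at its centroid (area-weighted mean
coordinate snapped to the nearest member vertex, ties to the lowest
index). A label is detected if any mark centroid of its own subject
lies inside it; false positives are counted in controls only. TPF
pools all labels (6 lesions over 5 subjects count as 6). The curve is
closed by prepending (0, 0) and extending horizontally to FPF = 1;
AUC is the trapezoid integral over FPF ∈ [0, 1], consistent with the
closed-form null AUC φ/(φ+1). FPF is provably non-decreasing along
the sweep and is asserted; TPF is *not* monotone under the centroid
criterion (merging clusters can move a centroid out of a label), which
is a property of the criterion, not a bug.

Wide lesion labels (strict labels dilated by 4 vertex rings) are the
evaluation ground truth; note that on coarse meshes 4 rings is a large
physical dilation (≈ 52 mm at level 3, ≈ 26 mm at level 4).

## Guessing null and inference

Each simulation run gives every subject N ~ Poisson(λ_max = 20) marks
at uniformly random vertices with activation levels u ~ U(0, 1); the
operating point at leniency ℓ uses marks with u ≤ ℓ — a monotonically
coupled uniform marking process whose expected curve is exactly
TPF = 1 − (1 − FPF)^φ. Activation levels are sampled so that expected
FPF is uniform across the sweep (ℓ = −log(1−f)/λ_max, 256 levels),
which resolves the strict region properly; the truncation error of
finite λ_max is e^(−20). Unbiasedness against the closed form is
verified to within 3 standard errors at φ ∈ {0.01, 0.1, 0.2, 0.5, 1}
(200 labels, 200 controls, m = 500, level-4 template). Marks are
vertex-uniform while φ is an area ratio; on the quasi-uniform
icosphere the two measures agree to ≈ 1% for labels of ≳ 50 vertices,
which is why these checks run at level 4.

Cohort p-values are p = (b + 1)/(m + 1) with ties counted toward b
(conservative); m = 10⁵ gives a floor of ≈ 10⁻⁵. Bonferroni adjustment
is min(1, k·p) over the condition family. Per-lesion sensitivity uses
the FPF at the strictest detecting threshold, converted to the chance
probability 1 − (1 − FPF_detection)^φ.

## Known limitations

* **Mild anticonservatism of the GLM pipeline against the guessing
  null.** The guessing null assumes every subject produces marks at the
  same intensity. Vertex-wise GLM z-maps violate this: each subject's
  global residual offset (the random intercept that covariates do not
  explain) shifts its whole map, so some subjects are mark-rich and
  others mark-free at a given threshold, raising TPF at matched FPF.
  On zero-effect cohorts (level-3 template, 30 controls, 2 lesions,
  400 seeds) the rejection rate at α = 0.05 is 0.075 rather than
  ≤ 0.07, with detector null AUC mean 0.101 vs guessing-null 0.065;
  recentring each z-map removes the effect completely
  (`analysis/04_null_calibration.py`). Classifier maps are per-subject
  z-scored and do not carry this exposure. Users comparing GLM maps
  against this null on real data should expect the same mild optimism.
* The centroid criterion makes TPF non-monotone in the threshold; AUC
  remains well defined but single operating points should be read with
  care.
* Smoothing FWHM below the mesh edge length saturates at the mesh
  resolution.
* The Mahalanobis detector refits a robust covariance per left-out
  control, which dominates runtime for large control groups.

## Problem sizes used by the test suite

The statistical suites run at sizes chosen to keep Monte-Carlo error
well below the tested tolerances: the cohort-null mean (6 labels,
94 controls) uses 10⁴ runs; closed-form agreement uses 200 labels ×
200 controls × 500 runs per φ on the level-4 template; null
calibration uses 400 zero-effect cohorts at level 3 with 30 controls;
power and GLM-calibration checks use level-3 cohorts with 30–94
controls. The acceptance script reproduces the analytic anchors and
the 10⁴-run cohort null in a few seconds.
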