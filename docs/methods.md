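# Methods

This note records the models, conventions and design decisions behind
`hetex`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
do not themselves compute.

## Pipeline model

A heterogeneity index is a scalar functional of the spatial arrangement of
tracer uptake inside a delineated volume of interest (VOI). All tumor-wise
indices share one preprocessing step, *redigitization*: the VOI intensities
are binned into L integer gray levels by equal-width binning over the VOI's
own range,

    level(v) = 1 + floor((v − v_min) / (v_max − v_min) · L),  clamped to L,

with a constant VOI mapping to level 1 everywhere. Binning is VOI-relative
(not absolute-SUV), which makes the texture families invariant to positive
affine rescaling of the intensities; absolute binning is deliberately not
offered. Default L = 64, configurable via `quantization.levels`. The
parametric mapper re-bins each sliding cube locally with its own min–max
and a small L (default 8), because a 27-voxel cube cannot populate 64 bins;
the cube is treated exactly like a tumor VOI otherwise.

## Parent-matrix conventions

Choices that the index definitions leave open are fixed as follows:

- **Directions.** 3D pairing and runs use the 13 unique direction vectors
  of the 26-neighborhood (modulo sign) at Chebyshev distance 1 (config
  `matrix.distance`). Co-occurrence accumulates both orders of every pair,
  so the matrix is symmetric by construction and pooled over directions
  (per-direction averaging is not used).
- **VOI closure.** Only voxels inside the mask enter any pair, run, zone or
  neighborhood; the image outside the VOI never contributes.
- **Connectivity.** Zones and neighborhoods use 26-connectivity
  (`matrix.connectivity`); dependence counts tolerate level differences up
  to `ngldm.a` (default 0), and a voxel with no in-VOI neighbor contributes
  a dependence count of 0 rather than being dropped.
- **Index-space geometry.** Neighborhoods ignore anisotropic spacing (no
  resampling). This is a documented limitation; spacing *is* honored
  wherever physical units matter (volume, TLG, SUL_peak sphere,
  phantom geometry).
- **2D families.** Texture spectrum and texture feature coding are defined
  on the planar 8-neighborhood and are computed slice-wise; a VOI with no
  slice-interior voxel raises an error for those families.
- **Normalized co-occurrence.** The "normalized" variant standardizes the
  gray-level values to zero mean and unit variance under the matrix
  marginal before the moment-based indices are formed; correlation is then
  E[z_i z_j]. This is one defensible reading of the normalization; it is
  flagged in the docstrings.
- **Texture feature coding.** The published scheme is followed
  structurally: for each interior voxel the 8-neighborhood is split into 4
  connected pairs along the planar directions; each pair's two successive
  differences are thresholded (|Δ| ≤ `tfc.delta`, default 0) into sign
  pairs and mapped to gradient-variation classes (none / one-sided /
  monotone / extremum); the voxel code is the mixed base-4 aggregate.
  The three TFC scalars are implementation-defined conventions documented
  in the docstrings: coarseness = fraction of zero-variation codes,
  homogeneity = angular second moment of the code histogram, mean
  convergence = mean absolute code deviation in SD units. Code similarity
  in the TFC co-occurrence family is the diagonal mass of the code-pair
  matrix.

## Index conventions

- Entropies are base 2 (bits) everywhere.
- Moments use the population denominator n; the bias-corrected skewness and
  kurtosis use the standard small-sample factors (verified against scipy in
  the tests). Kurtosis is non-excess (Gaussian → 3).
- Run percentage divides the run count by voxels scanned
  (n_voxels × n_directions); zone percentage divides zones by n_voxels.
- SUL_peak rasterizes a 1 mL sphere (radius 6.2 mm) in index space from the
  voxel spacing and reports the maximum sphere-mean over VOI centers,
  scaled by a caller-supplied lean-mass/body-weight ratio that defaults to
  1 with a warning (the lean-mass formula is a caller decision, as is the
  SUV decay-correction reference time — both enter only through
  `PatientContext` / config inputs).
- Degenerate values are guarded, never NaN: zero-variance correlation and
  mean convergence return 0 with a warning; NGTDM divisions carry an
  ε = 1e−12 guard, so a perfectly homogeneous VOI reports coarseness 1/ε.
  Batch runs log the warnings per subject instead of failing.

## Segmentation

Region growing returns the 26-connected component of
{v : image(v) ≥ threshold} containing the seed (closed inequality, so an
SUV-2.5 threshold includes the contour value itself). Fuzzy C-means runs on
intensities within a caller ROI (which stands in for a physician's manual
pre-outline excluding benign hot tissue): fuzzifier m = 2, convergence when
the maximum membership change drops below 1e−5, centroids initialized from
intensity quantiles for determinism, falling back to an even spread over
[min, max] when the quantiles collapse on heavily imbalanced data. The
tumor is the highest-centroid cluster; cluster count defaults to 2. These
FCM defaults are package choices, documented here because the method's
common usage does not fix them.

## Evaluation

Each index is scored independently against a binary outcome. AUC is
computed by the tie-corrected (midrank) Mann–Whitney formula, which equals
the trapezoidal area under the empirical ROC exactly (property-tested
against an independent implementation). AUCs are *oriented*: values below
0.5 are reported as 1 − AUC with orientation −1, since either direction of
an index can be prognostic. The operating point maximizes Youden's
J = sensitivity + specificity − 1, ties resolved toward higher sensitivity.
Group comparison uses the Kruskal–Wallis rank test (scipy) with the
all-identical degenerate case mapped to H = 0, p = 1. No multiple-testing
correction is applied by default, matching the uncorrected per-index
reporting convention; a Benjamini–Hochberg column is available opt-in.

A calibration caveat: the chi-square reference for H is asymptotic. At
group sizes around 10 its discreteness is strong enough that a
2000-simulation Kolmogorov–Smirnov test legitimately rejects uniformity of
the null p-values; the calibration check therefore runs at 50 per group,
where the approximation is accurate. This is a property of the test, not of
the implementation.

## Synthetic phantoms and the cohort design

Phantoms place spherical lesions (world-space radius, so spacing-aware) on
a PET-like grid: default 26×24×24 voxels at (3.3, 4.7, 4.7) mm spacing,
background SUV 1, lesion SUV near 5 — roughly the uptake and voxel geometry
of clinical whole-body FDG-PET. A fragmented lesion is partitioned into k
Voronoi cells around random interior sites; cell values are offset
uniformly within ±spread and re-centered so the lesion's voxel-mean uptake
is exact. Noise is additive Gaussian (default SD 0.01 SUV for cohort
phantoms — small relative to the zone contrast, as the texture signal of
interest here is structural, not noise-driven); an optional Gaussian blur
emulates scanner resolution. The phantoms reproduce spatial uptake
structure only — no sinograms, reconstruction, or count statistics — so
green tests demonstrate computational correctness, not robustness to real
PET noise and resolution.

The two-group cohort generator (default 9 + 9 subjects) is built so that
mean uptake is uninformative *by construction* while texture is
informative: group 0 lesions are uniform, group 1 lesions are fragmented
(12 zones, spread 2·effect SUV), and the per-subject base uptake values
(Normal, mean 5, SD 0.5) are drawn once and assigned to both groups as
matched pairs. The pairing makes the SUV_mean score sets nearly identical
across groups, which pins its AUC near 0.5 deterministically — with only 9
subjects per group, a merely *exchangeable* construction would let the
oriented null AUC exceed 0.7 in a sizeable fraction of draws, defeating the
purpose of a mean-matched design. `effect = 0` removes the fragmentation
and makes the groups fully exchangeable.

## Problem sizes

Default problem sizes were chosen to exercise every code path at desk
scale: lesions of ~340 voxels (25 mL), cohorts of 18 subjects, oracle
comparisons exhaustive over all 2×2 3-level images plus ~150 random images
up to 6×6 (2D) and 5³ (3D), 20 cohort seeds, 2000 null simulations. A full
72-index extraction takes ~15 ms; the acceptance script completes in a few
seconds.

## Known limitations

- Oblique DICOM orientations are not supported (axis-aligned axial
  geometry is assumed); multi-frame/enhanced DICOM and PACS retrieval are
  out of scope.
- RT-STRUCT rasterization uses voxel-center containment (even-odd rule);
  partial-volume effects at contour boundaries are ignored.
- Distances > 1 reuse the same 13 directions scaled by the step; arbitrary
  direction sets are not exposed.
- Wavelet-based families are not implemented.
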