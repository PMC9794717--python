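# Methods

This note documents the models, defaults and numerical choices behind
`mmlnm`, in the order data flows through the pipeline.

## Synthetic cohort: what it emulates, what it does not

Lesion network mapping needs two datasets that cannot ship with a package:
a normative cohort (resting-state 4D series plus a diffusion
principal-direction/fractional-anisotropy field per subject) and a patient
cohort (lesion masks plus bounded behavioral scores). The generator
reproduces the *statistical structure* the downstream estimators rely on,
not the biophysics:

- **Functional series** are zero-mean Gaussian white noise per timepoint,
  optionally smoothed spatially (`spatial_corr`, the Gaussian sigma in mm,
  parameterizes the spatial correlation structure; smoothing per timepoint
  leaves time uncorrelated) and renormalized to unit marginal variance.
  Designed co-fluctuation is injected explicitly: voxel sets passed as
  `networks` share an additional common time course of standard deviation
  `network_amplitude`. There is no hemodynamic response, physiological
  noise, drift or motion structure; FD/DVARS traces default to zero and are
  supplied explicitly when censoring behavior is under test.
- **Direction/FA fields** rasterize polyline "tracts" with a tubular radius
  (default FA 0.6 inside, 0.05 outside; in-tract voxels carry the local
  unit tangent, background voxels a seeded random unit vector). No
  diffusion signal, crossing-fiber or bedpost modeling.
- **Lesions** are binary balls; size in cm³ is exactly voxel count × voxel
  volume. Real lesion geometry (vascular territories, irregular borders) is
  a non-goal.
- **Behavior** comes from a linear latent model: per-score latent =
  intercept + features·weights + centered-confounds·effects + Gaussian
  noise, discretized by the instrument rules below. Missingness is
  completely at random, applied to scores only — the mechanism in real
  cohorts is unknown; nothing here models informative missingness.

Default cohort conditions follow the observed stroke sample the method was
designed for: score intercepts (15.2, 26.2, 28.6, 6.7) at the cohort means
of ARAT/FMA-UE/Em-NSA/PTT; age ~ N(68.8, 14.0) clipped to 28–92 years;
days-since-stroke (TBSAA) ~ N(25.6, 20.3) clipped to 4–64; lesion sizes
span ~0.3–256 cm³. Confound effects default to values reproducing the
reported sign and rough size of the confound–score correlations: TBSAA
raises Em-NSA (+0.22/day, r ≈ +0.3), lesion size lowers Em-NSA (−0.11/cm³,
r ≈ −0.4) and raises PTT (+0.021/cm³, r ≈ +0.4); age has no direct effect.

**Instruments.** ARAT is 19 items in {0,1,2,3} (max 57), FMA-UE 33 items in
{0,1,2} (max 66; only the 0–66 range is prescribed — the 33×2 decomposition
is a documented stand-in), Em-NSA 5 modalities × 4 contact points graded
0/1/2 (max 40). Items are filled cumulatively (Guttman-style) from the
rounded latent total, so every item respects its own range and the total
equals the clipped latent. PTT is a touch threshold in mA, clipped to
(0, 10] with a floor of 0.1 mA, and set to 11 when the latent threshold
exceeds 10 mA (nothing felt at maximal stimulation); higher PTT is worse.
The observed PTT range in patients (1.8–11) is data-dependent and not
enforced.

**Association fixture.** `make_association_fixture` builds patient feature
maps as random combinations of five smooth spatial patterns (Gaussian
sigma 1.5 voxels, unit variance) plus voxel noise (sd 0.6) on a 14×14×12
grid of 2 mm voxels; the loading on pattern 1 is the latent disconnection
burden driving behavior with score loadings (−10, −11, −7, +2.6) and noise
(9, 10, 7, 1.2). On the standardized scale this makes PTT clearly dominant
(|loading|/noise ≈ 2.2 vs ≤ 1.1), so "recover the dominant score" is a
well-posed check; the loadings' signs encode that disconnection lowers the
three performance scores and raises the touch threshold. Passing recovery
tests on this fixture demonstrates that the estimator chain is consistent
under its own assumptions (linear map, additive noise, MCAR missingness) —
it says nothing about robustness to the nonlinearities, spatial artifacts
and confound structure of real imaging data.

## Functional disconnection

- **Censoring**: a volume is censored when FD > 0.2 mm or the backward
  difference of DVARS > 0.75%; the derivative form is our reading (the rule
  is stated as a "derivative of the root-mean-squared variance"), so the
  first volume can only fire on FD. One volume before and two after each
  hit are censored too (clamped at the ends); the series is split into
  consecutive 5-volume segments, contaminated segments are dropped, and so
  is the first segment unconditionally. A trailing partial block counts as
  a segment and is kept if clean.
- **Nuisance + band-pass**: both data and regressors are filtered with the
  same zero-phase Butterworth band-pass (0.01–0.08 Hz, order 4), then the
  filtered nuisance set plus intercept is projected out by OLS — an
  equivalent one-step band-limited projection. No specific filter is
  prescribed by the method; Butterworth order 4 is the package's choice.
  `sosfiltfilt` runs with even-reflection padding: on series of a few
  hundred volumes the dominant stop-band leakage is boundary-transient
  energy, and even padding keeps it under 1% for a pure out-of-band tone
  (odd padding leaves ~3%).
- **Seed series**: mean over lesion ∩ gray-matter voxels; an empty
  intersection falls back to whole-lesion averaging with a logged warning
  (or raises, by flag).
- **Fisher transform**: |r| is clipped to 1 − 1e−7 before artanh so exact ±1
  correlations stay finite; zero-variance voxels get z = 0 and are flagged.
- **Group T-map**: one-sample t = mean/(sd/√n) with ddof 1. Voxels with
  zero across-subject variance get t = 0 when the mean is 0 and a signed
  sentinel (±100, configurable) otherwise, flagged either way. The raw
  T-map is passed forward unthresholded.
- By default only the first six minutes of each series are used
  (configurable), applied after censoring.

## Structural disconnection

The tracker is the voxel-hop variant of fiber assignment by continuous
tracking: the direction is re-read from the currently occupied voxel and
one voxel-edge step is taken along it, landing on the nearest voxel.
Principal diffusion directions are sign-ambiguous, so each step the field
vector's sign is chosen to maximize alignment with the incoming direction,
and propagation from the seed runs both ways. A step is accepted only when
the landing voxel is inside the grid, passes the FA threshold (0.15), and
its aligned direction turns by at most 60° from the incoming direction —
an offending landing voxel is excluded, which places the last voxel of a
streamline adjacent to any sharp turning plane. `max_steps` defaults to
twice the grid diagonal in voxels to break pathological cycles. Seeds
below the FA threshold are skipped (count logged) rather than forced; the
patient map always marks lesion voxels themselves as visited (a lesion is
trivially connected to itself), then averages binarized per-subject
visitation maps. Sub-voxel interpolation of directions is out of scope and
documented as such.

## Features and behavior preparation

- Union masks take strict non-zero values per patient map; for functional
  T-maps this is near-universal coverage, which is expected and accepted.
- SC values are log-transformed as log(x + 1e−6) (the offset is
  configurable); lesion maps stay binary; FC T-values enter as-is.
- Column standardization is applied only when a matrix is destined for
  multimodal concatenation (unimodal runs are centered by the PCA step
  instead); zero-variance columns standardize to zero and are flagged.
- PCA is centered (full SVD); loadings are row-orthonormal and
  reconstruction at full order recovers the matrix to 1e−6.
- Imputation: scikit-learn's iterative (chained) imputer with extra-trees
  regressors, 100 trees, 10 rounds maximum, tolerance 1e−3, seeded.
  Observed cells are never modified; confounds are never imputed. These
  hyperparameters are package choices; only the algorithm family is
  prescribed.
- Confound regression: per-score OLS on (age, TBSAA, lesion size) with
  intercept; residuals are z-scored (population sd). Residual variance at
  numerical-noise level (≤1e−8 relative) counts as zero and is flagged
  rather than amplified.

## CCA, cross-validation and selection

- Only the first canonical pair is used throughout; a single T is reported
  per analysis. The pair is computed in closed form (Cholesky-whitened
  cross-covariance, leading singular pair); a relative ridge of 1e−8 on the
  within-set covariance diagonals keeps near-degenerate problems
  factorable, at the cost of shaving ~1e−8 off exact-unity correlations.
  Weights are unit-norm, signed so the behavioral weight of largest
  magnitude is positive.
- LOOCV pools one held-out pair of canonical variates per patient
  (centered with training means) and reports their Pearson correlation,
  T_cv. Fold weights are sign-aligned to the full-data y-weights; without
  alignment the pooled statistic is sign-ambiguous. This convention gives
  the null |T_cv| a wider spread (95th percentile ≈ 0.5 at n = 40) than an
  oracle-aligned statistic would have; permutation inference is unaffected
  because surrogates share the convention (measured type-I error 0.04–0.06
  at the 5% level). All folds are solved in one batched pass via rank-one
  downdates of the full-data Gram matrices.
- Permutations shuffle the rows of the X score matrix (Y fixed) and
  recompute the LOOCV statistic (in-sample by flag); p is the fraction of
  surrogates strictly greater than the observed value, with no +1
  correction, error bar sqrt(p(1−p)/#perm), and p = 0 reported alongside
  its floor 1/#perm. Default 1000 permutations.
- The order scan shares one permutation set across orders k = 1..k_max.
  Scan-level significance is a max-statistic test — observed max over k of
  T_cv against each surrogate's max over the same orders — so scanning
  many orders does not inflate the type-I error (a per-order gate at
  alpha = 0.05 measured 0.14 family-wise at k_max = 4; the max-statistic
  gate measures 0.04–0.06). Per-order marginal p-values are still reported
  in the scan table.
- Selection: when the gate passes, #Comp is the smallest order whose T_cv
  is within `t_cv_tol = 0.01` of the maximum. The tolerance implements
  parsimony: differences below it are LOOCV noise (observed drift ~5e−4
  across orders past the plateau), and exact-argmax selection lands on
  arbitrary high orders and dilutes the back-projected map with noise
  components.
- Ve is reported as the cumulative PCA explained-variance ratio at #Comp.
- Back-projection maps `loadings[:k].T @ x_weights` into the union mask,
  z-scores over the mask, and thresholds at |Z| > 2 (two-sided on the
  support, signed values preserved; one-sided by flag). Concatenated
  feature sets split at the recorded SC/FC boundary, each modality keeping
  its own union mask and reporting its median raw weight.

## Annotation and reporting

Hemisphere assignment is by voxel index against the midline plane of the
grid's `midline_axis` (lower index = left); voxels exactly on the plane
(odd axis length) are excluded from left/right totals. The lateralization
test is the uncorrected Pearson chi-square on the 2×2 (analysis ×
hemisphere) count table — the uncorrected statistic reproduces the
published values (82.70 exactly at printed precision, 2160.04 within
0.02%); Yates correction is available by flag. Cohort summaries use
Kruskal–Wallis for left- vs right-lesion score comparisons (hemisphere
from the lesion's center of mass) and Pearson correlations among scores
and against confounds. Left/right lesion-map similarity is computed as the
spatial correlation between the left-group frequency map and the
*mirrored* right-group frequency map by default; mirroring is our reading,
and the unmirrored comparison is available.

## Problem sizes

Default test and acceptance runs use grids of 8–21 voxels per axis,
normative cohorts of 1–20 subjects, 60-patient fixtures, k_max ≤ 10, and
99–199 permutations; calibration uses 200 null replicates at 99
permutations. These sizes make the full suite run in minutes while keeping
every statistical check at the sample sizes its expected behavior was
derived for.

## Known limitations

- The generator's realism limits: no hemodynamics, no diffusion signal, no
  realistic lesion shapes, MCAR missingness only.
- FMA-UE item structure is invented (only the total range is specified).
- The tracker's voxel-hop stepping differs from sub-voxel interpolating
  implementations; streamlines are voxel lists, not polylines.
- Only the first canonical pair is modeled; multiple pairs, sparse/kernel
  CCA and family-wise correction across analyses are non-goals.
- Published headline correlations from patient data (T = 0.38–0.56) depend
  on data this package does not ship and are not reproduced; the package's
  own checks are the property-based quantities in `scripts/acceptance.py`.
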