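# Methods

`hipporad` implements a hippocampal functional-radiomics analysis chain:
resting-state BOLD volumes → four derivative maps → 819 radiomics features
per map → redundancy pruning and LASSO selection → a rad-score and a
logistic-regression classifier → evaluation and clinical-association
statistics.  Because no patient data ship with the package, a synthetic
cohort generator provides study-like inputs with known planted effects; it
is first-class, tested code, not a fixture.

## Synthetic cohort model

Each subject is a 4-D grid (default 3 mm isotropic voxels, TR = 2 s, 230
time points — 240 acquired minus 10 equilibration frames).  Per voxel the
signal is a sum of band-limited components plus white noise:

* a **local synchrony** component `c(t)` shared by the whole bilateral
  hippocampal ROI (one signal per cohort draw, mirror-symmetric by
  construction), the quantity regional homogeneity responds to;
* a **homotopic** component `h_v(t)` shared only between a voxel and its
  x-mirror partner (independent across mirror pairs), the quantity VMHC
  responds to;
* independent in-band background signal outside the ROI, and i.i.d.
  Gaussian noise (`noise_sd`, default 1.0) everywhere.

Band-limited signals are sums of 6 sinusoids with frequencies drawn
uniformly in 0.01–0.1 Hz and random phases, normalized to unit variance —
the energy sits exactly where ALFF integrates.  Group effects are
multiplicative attenuations of the shared components in the cognitively
impaired (CI) group: `effect_synchrony` and `effect_homotopy` are fractional
reductions in [0, 1].  With both at 0 the groups are exchangeable, which is
the null used for calibration checks.  One global seed fans out to
per-subject child generators through `SeedSequence(seed, spawn_key=(stream,
subject))`, so cohorts are bit-reproducible while subjects stay independent.

A deliberate consequence of attenuating a ROI-wide shared signal is that
*every* correlation-based metric responds to `effect_synchrony` (degree
centrality sums the same attenuated correlations ReHo ranks), and the total
variance change also moves ALFF.  The generator therefore supports
parameter-recovery tests (a planted effect is detected; a null is not) but
does not define a ground-truth ordering *between* metrics — real cohorts, in
which different metrics capture genuinely different physiology, may behave
differently.  Spatial normalization, head motion, hemodynamic response
shapes and T1 anatomy are not modelled.

The clinical table plants a MoCA separation by construction (CI < 26 ≤ CP,
with `planted_moca_gap` controlling CI severity spread) and draws the other
scales as `mu_g + sd_g·(ρ·z_effect + sqrt(1−ρ²)·ε)`, where `z_effect` is the
standardized injected imaging effect and `ρ = clinical_corr` (default 0.3).
Scales without an established group difference in this clinical picture
(HAMA, HAMD, UPDRS-III, NMSS, PDQ-39, BMI, disease duration) share one mean
across groups, so any group information they carry flows only through the
`ρ` channel; MoCA, education and age carry explicit group differences.
Values are clipped to each instrument's range.

## Derivative maps

All four maps start from detrended, band-passed data.  The band-pass is an
ideal FFT filter keeping 0.01 ≤ f ≤ 0.1 Hz (DC removed with the trend); an
ideal filter keeps the ALFF oracle exact and attenuates stop-band energy
completely.  Spatial smoothing (Gaussian, FWHM 6 mm, σ = FWHM/(2√(2 ln 2))
per axis, reflective boundaries) is applied to the *input* for ALFF and VMHC
but not for ReHo and DC, whose maps are smoothed after z-transformation —
smoothing the input would mechanically inflate local rank concordance and
short-range correlations.  Smoothing and temporal filtering act on different
axes and commute, so the relative order of those two steps is immaterial.

* **ALFF**: mean over in-band bins of √PSD, with the one-sided raw
  periodogram `P_k = 2·TR/n·|X_k|²` (no Welch windowing); ALFF is therefore
  exactly linear in signal amplitude.
* **ReHo**: Kendall's W over a voxel and its 26-connected in-mask
  neighbours, `W = 12S / (m²(n³−n) − m·ΣT_i)` with midranks and the standard
  tie correction (ties are measure-zero for continuous data but synthetic
  inputs must be deterministic).  Edge voxels use their reduced in-mask
  neighbourhood; an isolated voxel gets 0 with a warning.
* **VMHC**: Pearson correlation between each voxel and its x-mirror; the
  mask must be exactly mirror-symmetric (checked, with the offending voxel
  count reported).
* **DC**: weighted degree, the sum over all other in-mask voxels of
  correlations strictly greater than +0.25 (one-sided; negative correlations
  never contribute).  Constant voxels contribute 0 with a warning.

Each map is z-transformed within the brain mask using the population
(divide-by-N) standard deviation — a convention that had to be fixed; it is
documented here and asserted in tests.  A constant raw map (possible only
for degenerate toy inputs) degrades to an all-zero z-map with a warning
rather than an error.

## Radiomics features

One map yields exactly 819 features: 18 first-order + 73 texture on the
original image, and the same 91 on each of 8 sub-bands of a one-level
undecimated 3-D wavelet transform (8 × 91 = 728).  Choices that the printed
totals do not pin down, fixed here:

* **Discretization**: fixed bin *count* (default 32), equal-width over the
  in-ROI min–max range, recomputed per image (original and each sub-band).
  The maps are z-scored with arbitrary units, so a fixed bin width would be
  meaningless.
* **Wavelet**: Coiflet-1, one level, undecimated (à-trous filters applied
  separably per axis with mirror extension), so every sub-band stays on the
  original grid and the ROI mask applies unchanged.  Sub-band letters are
  ordered (x, y, z); the basis is a parameter.
* **GLCM roster (22)**: Autocorrelation, ClusterProminence, ClusterShade,
  ClusterTendency, Contrast, Correlation, DifferenceAverage,
  DifferenceEntropy, DifferenceVariance, Id, Idm, Idmn, Idn, Imc1, Imc2,
  InverseVariance, JointAverage, JointEnergy, JointEntropy,
  MaximumProbability, SumEntropy, SumSquares.  The widely used de-facto
  standard set is trimmed of its redundant members (SumAverage equals
  2·JointAverage on a symmetric matrix; MCC is non-classical and costly;
  Dissimilarity and SumVariance are deprecated duplicates of
  DifferenceAverage and ClusterTendency) — this 22-member roster is the
  composition consistent with the 73-texture / 819-total identities.
* **Aggregation**: GLCM and GLRLM accumulate over the 13 unique distance-1
  3-D directions and are *summed* before feature computation; GLSZM zones
  and GLDM/NGTDM neighbourhoods use 26-connectivity.  Run percentage is
  normalized by ROI size × 13 so it stays in (0, 1].
* **Degenerate conventions**: Correlation of a constant ROI is 1 (maximal
  homogeneity); NGTDM Coarseness of a uniform ROI returns the sentinel 1e6;
  GLDM dependence is stored as count + 1 (the voxel itself) so
  small-dependence emphases stay finite; a single-voxel ROI produces
  all-zero GLCM features with a warning.  Percentiles interpolate linearly
  between order statistics.

Every texture matrix is validated against a brute-force enumeration oracle
(pair enumeration, run scanner, flood fill, neighbour counting) in the test
suite.

## Selection and models

Feature normalization is min–max to [0, 1] with *training-cohort* statistics
(validation transformed with the same parameters and clipped); constant
training features are dropped.  Redundancy pruning is greedy at Spearman
|ρ| > 0.9: the currently worst pair is found, and the member with the larger
mean |ρ| to the retained set is dropped (exact ties drop the
lexicographically later name), which makes the outcome deterministic and
column-order independent.

LASSO treats the binary label as a continuous response,
`(1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁`, with λ selected by 10-fold label-stratified
CV over a 100-point log grid from `λ_max = max_j |X_jᵀ(y − ȳ)|/n` down to
10⁻³·λ_max, minimizing mean CV squared error (not the 1-SE rule).  The
minimum-MSE rule is known to admit a few small-weight decoys; the tests
assert what it actually guarantees — full support recovery with an
order-of-magnitude weight gap to decoys.  If the CV-optimal penalty selects
nothing (possible on null data), the smallest-CV-error penalty with ≥ 1
non-zero coefficient is used so downstream models always exist.  Selection,
normalization, the Youden threshold, SMOTE and model fitting all see the
training cohort only; the split is stratified 7:3 (train size ⌊0.7n⌋, as
in the worked 89-subject case: 62/27).

The **rad-score** is the selected features' linear combination; its
operating threshold maximizes Youden's J (ties prefer higher sensitivity,
then the lower threshold) on training scores.  The **LR model** is
maximum-likelihood logistic regression with a tiny ridge (α = 1e-4,
intercept unpenalized) for stability on separable synthetic data, fit on a
SMOTE-balanced training set (synthetic minority points interpolated between
k ≤ 5 nearest minority neighbours).  Evaluation reports Mann-Whitney AUC
with a DeLong 95 % CI, accuracy/sensitivity/specificity with Wilson CIs
(positive = CI, called when score > threshold; LR threshold 0.5), paired
DeLong AUC comparisons, decision-curve net benefit
`TP/n − FP/n·pt/(1−pt)` with treat-all/treat-none references, and exact
linear-model SHAP (`φ_ij = w_j(x_ij − x̄_j)` over training-mean background).
Training metrics are reported on the original (pre-SMOTE) training data.

## Clinical associations

Partial correlation residualizes both variables on the covariates (plus
intercept) and correlates the residuals; `t = r·√((n−2−k)/(1−r²))`,
two-sided.  Bonferroni uses `min(1, p·n)` with a default family size of 7
tests, configurable.  Group comparisons: chi-square without continuity
correction for categorical variables; for quantitative ones a Shapiro-Wilk
gate (α = 0.05 in both groups) routes to the pooled-variance t test or the
Mann-Whitney U test, with explicit overrides available.

## Problem sizes and reproducibility

Tests and the acceptance script run the end-to-end pipeline on 12³ grids
with 64 time points and cohorts of 30–60 subjects — small enough to iterate
quickly, large enough that a 0.8 planted attenuation yields validation
AUC > 0.9 while 20 zero-effect cohorts centre on AUC 0.5.  Definitional
oracles use grids ≤ 8³.  Every stochastic step takes an explicit seed; the
pipeline manifest records the config hash and per-file SHA-256 digests, and
re-running a config reproduces identical digests.

## Known limitations

Synthetic BOLD has no hemodynamic model, motion, physiological noise
spectra, or anatomical variability; passing tests demonstrate the
*computational* correctness of each stage and the pipeline's ability to
recover planted correlation-structure effects, not clinical performance.
The 73-texture membership beyond the features named in the field's tables is
fixed only up to the printed counts.  DC is computed within the full brain
mask (the mask is a parameter).  The LASSO response is the 0/1 label, not
logistic loss, mirroring the named procedure it reimplements.
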