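# Methods

## Mediation path model

Given exposure X, mediator M, outcome Y and covariates Z, `fit_paths` fits
three OLS (or robust IRLS) regressions on the listwise-complete analysis
sample after z-transforming X, M, Y and all numeric covariates (sample SD,
n−1 denominator):

* `M ~ 1 + X + Z` → path **a**
* `Y ~ 1 + X + M + Z` → paths **b** (on M) and **c′** (on X)
* `Y ~ 1 + X + Z` → path **c**

The indirect effect is **ab = a·b**. With OLS and identical covariates in
all three models, c = c′ + ab holds exactly (verified to 1e−10 in tests);
robust fitting breaks the exact identity, which is expected.

Rank-deficient designs are rejected with the collinear columns named.
Degenerate inputs (constant columns) are rejected at z-scoring time.

### Bootstrap inference

`bootstrap_mediation` resamples participants (rows) with replacement,
refits all paths per resample — re-z-scoring within each resample, because
standardization is treated as part of the estimator (a flag restores fixed
scaling) — and computes **bias-corrected percentile** quantities per path:

* ẑ₀ = Φ⁻¹(clip(#{θ\* < θ̂}/B)), proportions clipped to
  [1/(B+1), B/(B+1)];
* the BC bound at level α uses the bootstrap quantile at
  Φ(2ẑ₀ + z₍α₎) (or its upper counterpart);
* the p-value is the smallest α at which the bound in the tested direction
  excludes zero, found by binary search to 1e−4 (so reported p-values floor
  at 0.0001). One-tailed tests use the a-priori direction for ab
  (`expected_sign_ab`; an estimate of the opposite sign yields p ≥ 0.5) and
  the sign of the point estimate for the other paths; two-tailed p-values
  double the one-tailed value, capped at 1.

The correction is BC, not BCa: no acceleration constant is estimated, since
the method description is "bias-corrected". Resamples in which any fit
degenerates (a constant column after resampling, or a numerically singular
Gram matrix) are redrawn so B stays fixed; the redraw count is reported and
the run aborts if failures exceed 10% of B. Everything is deterministic
under the spec seed. Simulation checks in the test suite: one-tailed type-I
error ≤ 0.08 at the null (a = 0.5, b = 0, n = 200), power ≥ 0.95 at
(a = 0.5, b = 0.4, n = 500), and 95% BC interval coverage for ab within
[0.90, 0.98] at n = 300. The two-tailed bootstrap p agrees with the Sobel
large-sample test within 0.02 at n = 2000, and `sobel_test` is provided as
the bootstrap-free reference.

The non-robust bootstrap is fully vectorized (batched Gram-matrix solves
across resamples, chunked to bound memory), which is what makes the
simulation-based calibration checks and the 24-ROI analyses cheap on one
CPU. The robust path loops per resample and is proportionally slower.

### Robust regression

`irls_bisquare` implements iteratively reweighted least squares with Tukey
bisquare weights, tuning constant 4.685 (the conventional 95%-efficiency
value), residual scale MAD/0.6745 recomputed per iteration, convergence
when the maximum coefficient change falls below `tol`, and a warning flag
on non-convergence. It matches `statsmodels` RLM with the same settings to
~1e−4 in tests. Observations beyond 4.685·scale receive exactly zero
weight.

## Behavioral scoring

The SPR trial schema carries four region RTs; analyses use the
**relative-clause region only** (the other regions are retained but unused).
`rt_overall`/`acc_overall` pool all trials over conditions; with the default
equal trial counts the pooled RT equals the mean of the per-condition means
exactly. SDS measures are computed on raw condition means
(rtSDS = SR − OR; accSDS = OR − SR) and z-scored afterwards for modeling,
preserving their printed definitions; more negative SDS means relatively
worse performance on the harder object-relative structure.

Outlier exclusion marks a participant iff |value − cohort mean| > k·SD
(k = 3 by default) **in both conditions of the same measure family** (both
RT means, or both accuracies). Mixed extremity (e.g., RT in one condition,
accuracy in the other) does not exclude; exclusion statistics are computed
once on the full sample with no iterative re-exclusion; a zero-SD condition
excludes nobody on that family. Exclusion operates on raw summaries, and
whether "accuracies" means the per-condition pair (assumed here) rather
than overall accuracy is an interpretation documented in the code.

## Imaging features

* `nyquist(tr) = 1/(2·tr)` — 0.303 Hz at the default TR of 1.65 s.
* `gaussian_smooth` converts FWHM in mm to per-axis sigma in voxels
  (fwhm / (voxel·2√(2 ln 2))), with nearest-edge boundary handling so
  constant volumes are preserved; smoothing applies to gray-matter maps
  only (default 8 mm), never to pALFF inputs.
* `roi_aggregate` is the plain arithmetic voxel mean per atlas label; any
  integer-labeled volume with a label→(name, hemisphere) map is accepted.
* `compute_palff`: per in-mask voxel, linear detrend (default on), a
  rectangular-window periodogram of the full series (no Welch
  segmentation), then the ratio of summed power over bins with
  band_low ≤ f ≤ band_high (closed interval on the FFT's natural grid, no
  interpolation) to summed power over all positive-frequency bins (DC
  excluded by default; both toggleable, since reference descriptions are
  silent on detrending). "Power" is the squared FFT magnitude, following
  the ratio's verbal definition; an `amplitude` toggle switches to the
  |FFT| variant used by classic ALFF code. The periodogram is one-sided
  with Parseval-preserving weights, so total power including DC equals the
  time-domain sum of squares. The final map divides by the mean raw ratio
  within the brain mask (mask mean exactly 1); out-of-mask voxels are 0;
  all-zero series get ratio 0 with a warning. For white noise the expected
  raw ratio is the in-band bin fraction ≈ (0.08 − 0.01)/0.303, which the
  tests verify against a flat-spectrum oracle.

## Pipeline

The default ROI set is the 24-region language parcellation: three bilateral
groups of four subregions (IFG pars triangularis/opercularis/orbitalis +
MFG; MTG/STG and their poles; pMTG/pSTG/SMG/AG). Covariate policy: sex and
education in all models; TIV only in GMV models; memory scores optionally
added singly or jointly; the memory-mediation analysis reuses the same
machinery with Y = WM (covariate STM) or Y = STM (covariate WM).

Indirect-effect p-values are BH-FDR adjusted **separately within each
hemisphere × modality family** (each `run_roi_mediation` call handles one
modality, grouping by hemisphere; joint adjustment demonstrably differs and
is covered by a test). `t_indirect` = bootstrap mean / bootstrap SD is a
descriptive, not inferential, statistic used for stat-map coloring. Per-ROI
bootstrap seeds are derived from (master seed, ROI name) via SHA-256, so
adding or removing ROIs does not shift other ROIs' resamples; model Ns can
differ across ROIs under listwise deletion and are reported per row.

## Synthetic data: what it emulates, and what it does not

* **Cohort.** Ages from a two-component normal mixture — (30, 7) and
  (67, 8) years with weights 0.45/0.55 — clipped to [20, 80]; this matches
  the bimodal adult lifespan design and reproduces an overall age SD near
  20 years. Memory z-scores are β·z_age + √(1−β²)·ε with β = −0.61 (WM) and
  −0.54 (STM), mapped to score scales 107.96 (13.88) and 26.17 (6.39).
  Sex ~ Bernoulli(0.74 female), education a clipped discrete 1–6 scale
  (mean 5.1, SD 1). TIV spread is not reported in any reference table;
  1450 ± 130 ml is a plausible adult default and is flagged as invented in
  the config docs.
* **Trials.** Relative-clause RTs are lognormal (positive, right-skewed):
  per participant, log-RT = ν_c + u + v_c + β_c·z_age + σ_w·ε with shared
  participant speed u, an OR-specific component v, log-scale age slopes
  β_SR = 0.10 and β_OR = 0.122, and trial noise σ_w = 0.45. ν and the
  variance components are solved **against the empirical cohort** (moments
  of exp(β·z_age) are computed from the realized ages rather than assumed
  normal), so the across-participant mean and SD of the 24-trial summary
  match the configured targets (OR 2.89 s (1.28); SR 2.43 s (0.99)) exactly
  in expectation. The slope defaults were fixed once from delta-method
  algebra to put the age correlations near r ≈ +0.27 (overall RT) and
  r ≈ −0.18 (rtSDS). Correctness is Bernoulli with
  logit p = μ_c + γ_c·(w·z_WM + √(1−w²)·ε), w = 0.5, where (μ_c, γ_c) are
  solved by nested Brent root-finds so the mean and the across-participant
  SD of accuracy (86.6% (8.4) OR; 89.7% (8.8) SR) match, accounting for the
  binomial floor at 24 trials; the WM share sizes the standardized
  WM→accuracy path near 0.35. The emulated dissociation — memory mediates
  the age effect on accuracy, while the age effect on reading speed is
  direct — is the structure the behavioral suite is expected to recover.
* **ROI features.** Non-planted ROIs: intercept + (−0.004/yr)·age + N(0,
  0.1) noise, giving strong negative age correlations as in adult gray
  matter. A planted ROI is built as M = a·z_age + √(1−a²)·u, and its b path
  is injected by replacing the designated outcome with
  c·z_age + Σ b_j·M_j + λ·e, where c is the original outcome's empirical
  standardized age slope, e its standardized age-residual, and λ restores
  unit variance — so the population standardized paths equal the planted
  (a, b) exactly and the planted ab is recoverable by direct OLS. When no
  nonzero b is planted the outcome is left untouched.
* **Phantom.** Three equal blocks along the first axis: 0.05 Hz sinusoids
  (random phase per voxel), 0.20 Hz sinusoids, and white noise, on a
  baseline of 100 with an optional noise floor; defaults 9×3×3 voxels,
  427 volumes, TR 1.65 s. Frequencies at or above Nyquist are rejected.

Not emulated: BOLD autocorrelation and physiological noise, realistic
cortical geometry, item-level psycholinguistic structure beyond condition
and age, question-type effects, and spatial correlation between ROIs.
Passing recovery tests therefore demonstrate the statistical machinery, not
robustness to realistic imaging artifacts.

## Problem sizes and numerical choices

Simulation studies in the tests use B = 500–1000 bootstrap replicates and
n = 200–500 participants (50–500 replicates per study), sizes at which the
Monte-Carlo error of the checked rates is comfortably inside the asserted
bounds; the reproduction script uses n = 5000 participants for the
calibration means. Bootstrap chunking caps resample arrays at ~2M rows.
Binary search for p-values terminates at 1e−4; BC interval endpoints use
linear-interpolation quantiles; near-singular batched Gram matrices are
detected via the determinant of the scale-free Gram (z-scored columns) at
1e−10.

## Known limitations

* The BC p-value convention (confidence-bound inversion) is self-consistent
  and oracle-tested, but other implementations use direct formulas that can
  differ in the third decimal.
* Single-mediator models only; no multiple-mediator decomposition, mediated
  moderation, latent variables, or sensitivity analysis for sequential
  ignorability — mediation here is associational unless the causal
  assumptions hold.
* Robust (IRLS) mode reports a·b from robust fits; no robust analogue of
  the exact total-effect decomposition exists.
* `p ≥ 0.5` for indirect estimates opposite to the declared direction is a
  convention of the one-tailed design, not evidence for the null.
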