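# Methods

This note records the models, conventions and numerical choices behind
`nfbpredict`, and what the synthetic benchmark does and does not
demonstrate.

## Online feedback and the learning index

The feedback channel is band-passed 0.5–45 Hz with a *causal* 4th-order
Butterworth filter (the online loop cannot see the future), and the SMR
band power is computed every `step_s` = 0.1 s from the trailing
`window_s` = 10 s window as the one-sided periodogram sum over bins with
centre frequency in [12, 15] Hz (endpoints inclusive, DC excluded),
scaled so a sinusoid of amplitude A on a bin centre has power A²/2. The
window is rectangular by default — the plainest reading of "an FFT of the
data window" — with the taper configurable. A signal of n samples yields
`floor((n − window)/step) + 1` power values.

The reward threshold for run r is the median power of run r−1 (the
baseline run 0 seeds the first threshold); a reward point is granted per
maximal above-threshold stretch lasting strictly more than 1 s, one point
per stretch regardless of extra length (the simplest self-consistent rule;
re-triggering behaviour is otherwise unspecified).

Per session, the per-run median powers are regressed on the 0-based run
index by OLS; the learning index LI is the mean slope across sessions, in
power units per run. Whether run 0 enters the regression is a flag
(default: included). Everything in the chain is linear in signal power, so
scaling the raw signal by c scales powers, medians and LI by c² — a
property the tests assert. Cohort-level normality of LI is checked with
Shapiro–Wilk; the screening stages use rank statistics regardless.

## Resting EEG features

Recordings are band-passed 1–100 Hz (zero-phase Butterworth),
re-referenced to the common average (the concrete reading of "a common
reference"), and cut into non-overlapping 1-s epochs. An optional
amplitude-threshold epoch rejector stands in for manual artifact review
and is off by default — synthetic data contain no artifacts, and ICA is
out of scope. PSDs use Welch's method: Hamming windows, 50% overlap,
1000-point segments at 1 kHz sampling (configurable for shorter test
signals); no per-segment detrending, so the estimator equals the plain
mean of modified periodograms that the test oracle implements. Relative
band power is the bin-sum PSD integral over the band divided by the
1–100 Hz integral (the preprocessing band; the denominator range is not
otherwise pinned down numerically).

Summarising epochs: relative powers are computed per epoch and channel,
standardized, and the across-epoch **median** is taken; nine scalp ROIs
average their member channels. The standardization is an affine map whose
mean/SD are pooled over *all epochs of the cohort* (per channel, band and
eye condition). Standardizing within a single recording instead — i.e.
z-scoring across that recording's epochs before the median — would reduce
every participant's value to a skewness statistic of their own epoch
distribution and destroy between-participant level ordering, which is the
quantity the screening correlates with learning; the pooled map leaves
ranks untouched while making values unit-free. Zero pooled dispersion
yields 0 with a warning.

## Resting fMRI features

All volumes live on a small abstract grid with a 3-mm isotropic
corner-origin affine; spatial normalisation is out of scope and every
statistic used is geometry-agnostic. Conventions follow standard practice:

* **ALFF** — mean of the one-sided FFT amplitude spectrum over
  0.01–0.08 Hz (band configurable; the field-default band rather than the
  0.01–0.1 Hz global filter), computed from the *unfiltered*, linearly
  detrended, smoothed series. Without detrending, drift dominates the
  lowest bins.
* **fALFF** — in-band amplitude sum over the (0, Nyquist] sum; invariant
  to intensity rescaling.
* **ReHo** — Kendall's coefficient of concordance W of a voxel with its 26
  neighbours, from the band-passed (0.01–0.1 Hz), *unsmoothed* series,
  with the tie-corrected formula `W = 12 S / (m²(T³−T) − m ΣT_j)`. Voxels
  near the mask edge use their available in-mask neighbours; below 9
  neighbourhood members the value is 0.
* Metric maps are z-standardized within the brain mask (mean 0, SD 1);
  ALFF/fALFF are computed from 6-mm-FWHM-smoothed data, ReHo maps are
  smoothed after standardization. σ = FWHM / (2√(2 ln 2)) per axis in
  voxel units, reflective boundaries.
* **FC** — spherical ROIs (8 mm radius; a voxel belongs if its centre is
  within the radius, boundary inclusive, intersected with the mask), mean
  series per ROI from the filtered data, Pearson correlations
  Fisher-z-transformed with |r| clipped at 1 − 1e-7 (a warning marks
  degenerate pairs); the diagonal is stored as 0 and never analysed.

## Screening

* EEG cells: Spearman (midranks) against LI with two-sided t-approximate
  p-values; Benjamini–Hochberg step-up across the full family of
  9 ROIs × 4 bands × 2 eye conditions = 72 cells (the family is a design
  choice; nothing smaller is defensible). Constant cells are excluded from
  the family with a warning.
* Volume maps: per voxel, intensity ~ 1 + LI + age + sex by OLS; the LI
  t-statistic is referred to a **Freedman–Lane** permutation null
  (residuals of the covariates-only model permuted and added back to its
  fit — the standard scheme for nuisance covariates). The two-sided voxel
  p-value is `(1 + #{|t*| ≥ |t|}) / (n_perm + 1)`; when n_perm ≥ n! the
  permutations are enumerated exhaustively and the estimator becomes
  exact. A hair of slack (1e-10 relative) makes floating-point ties count
  as exceedances, so p-values are conservative and exactly invariant to
  participant relabelling. Suprathreshold voxels (p < 0.005 — the
  sensible reading of a significance threshold) form 26-connected
  clusters, split by contrast sign; clusters below 50 voxels are dropped.
  Variance-smoothed pseudo-t is available but off by default: at desk
  scale the plain t is what the calibration tests characterise.
* Connectome edges: each upper-triangle Fisher-z edge is rank-transformed
  with LI and the covariates, residualized on the covariates, and the
  residual correlation tested at uncorrected p < 0.005 (no FDR, matching
  the emulated procedure; its liberality is visible in the null edge
  tests).

## Prediction

Feature sets: the FDR-selected EEG cells; mean intensities of significant
GMV/WMV clusters; significant ALFF cluster means; selected FC edges; and
their column-wise concatenation (multimodal). Each column and the LI are
z-scored across participants once, before cross-validation — deliberately
reproducing the emulated procedure, where selection and normalization see
the full cohort (the induced optimism is shared by all feature sets being
compared; per-fold normalization is available behind a flag for honest
benchmarking). A modality with no surviving feature contributes a single
fallback column (the z-scored mean of its candidate features), flagged
degenerate and warned about, so the feature-set comparison stays defined.

Models: linear SVR (C = 1, ε = 0.1), OLS, ARD regression and random
forest (500 trees, seeded); a one-column EEG set uses plain OLS instead
of the SVR, mirroring the emulated analysis. Leave-one-out predictions
are scored by MAE and Pearson r against actual LI. Two feature sets are
compared with Steiger's (1980) z for dependent correlations sharing the
actual-LI variable, using the correlation between the two prediction
vectors as the third correlation; the method is unnamed in the emulated
analysis, and Steiger's test is the standard choice.

A property worth knowing when reading LOOCV numbers: under the null
(features carry no information), the LOOCV correlation is systematically
*negative*, not zero — leaving out a participant with a high target value
lowers the training mean and hence their prediction. At n = 27 with an
OLS model the null mean r is ≈ −0.2. Zero is therefore an upper bound for
no-skill prediction, and the test suite asserts exactly that, with a
hand-rolled fold-loop oracle confirming the artifact.

## Synthetic cohorts

The generator's job is to make every planted relation *recoverable in
principle* by the analysis chain while keeping raw data realistic enough
to exercise each stage:

* A per-participant standard-normal factor g drives the true learning
  slope (`slope = 0.05 + 0.1·g`, power units per run — most simulated
  participants learn, some do not, matching the emulated cohort's mix).
  Each planted effect's latent is jointly Gaussian with g at the level
  `ρ_G = 2 sin(π ρ_S / 6)`, so a target *Spearman* correlation ρ_S is hit
  exactly in the copula; independent latent noise (`noise_sd`) attenuates
  it. Monotone maps from latent to signal amplitude then preserve ranks.
* NFB runs: unit-variance 1/f noise plus a 13.5-Hz oscillator whose band
  power is `base + slope × run_index` (floored above zero); run 0 is a
  no-trend baseline. With noise off, the engine recovers the slope to
  within the band-pass filter's ~1% gain error.
* Resting EEG: per channel, pink noise plus theta/alpha/SMR/beta
  oscillators with random phases; a planted effect scales the SMR
  amplitude of the target ROI's channels by `exp(0.35 × latent)`. The
  64-channel montage includes all 42 channels of the nine scalp ROIs.
* fMRI: Gaussian noise inside an ellipsoidal mask on a baseline of 100;
  ALFF effects add an in-band sinusoid whose amplitude is monotone in the
  latent, ReHo effects mix a shared band-limited course into a cluster,
  FC effects mix a shared low-frequency latent signal into both ROI
  spheres.
* Morphometry: smooth Gaussian random fields (σ = 1 voxel, field SD 0.05
  around 0.5); planted clusters add `0.2 × latent` plus small voxel noise
  — algebraically an `a + b×slope + noise` parameterization with
  b = 0.2 ρ_G.
* Ground truth (slopes and clean latents) is stored next to the cohort
  and consumed by no analysis function.

What the synthetic data do **not** emulate: eye/muscle artifacts, volume
conduction and realistic head geometry, head motion, physiological fMRI
noise spectra, spatial autocorrelation of real brains, or registration
error. Passing tests therefore certify the *statistical machinery* —
calibration, recovery, no leakage — not robustness to real-world
contamination.

A quantitative honesty point: with 100 volumes at TR 2 s, band-amplitude
estimation noise caps the per-voxel correlation between a planted ALFF
cluster and its latent at roughly 0.5–0.6 regardless of planted amplitude
(stronger amplitudes are eaten by the within-brain z-standardization,
whose SD the cluster itself inflates). Voxelwise detection at p < 0.005
with n = 27 needs per-voxel |r| ≈ 0.55, so synthetic ALFF clusters
screen in only marginally, seed-dependent — unlike morphometry clusters,
whose voxel noise is small, and EEG/FC features, which pool many samples.
The end-to-end demonstration reports whatever the screen honestly finds;
the permutation GLM's own calibration and recovery are validated
separately at large effect sizes.

## Problem sizes

Simulations in the tests and the acceptance script are scaled for a
single CPU: runs of 11–30 s (window 10 s), resting EEG at 250 Hz with a
256-point Welch segment, 10³–12³ grids, 40–100 volumes, 4–10 ROIs,
200–2000 permutations, 10–2000 simulated cohorts depending on the
property. The protocol structure (3 × 12 runs, two eye conditions, the
72-cell EEG family, covariate-adjusted GLMs) always matches the emulated
study; only durations, grid sizes and replication counts shrink.

## Known limitations

* EDF files are read (via MNE) but not written; the generator emits
  csv.gz matrices with TSV sidecars.
* The permutation GLM's random-permutation p-values are quantized at
  1/(n_perm+1); at 500 permutations the smallest attainable two-sided
  rate below 0.005 is 2/501 ≈ 0.004, which is what a correctly calibrated
  test shows (and what the calibration test asserts).
* The ReHo map loops voxels in Python; adequate up to ~16³ grids, not
  tuned for full-resolution brains.
* Missing-modality inputs degrade to flagged fallback feature sets rather
  than being dropped from the comparison.
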