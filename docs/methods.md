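# Methods

This note documents the models, conventions and numerical choices behind
`fnirslab`, and what the synthetic-data tests do and do not establish
about real recordings.

## Data model

A `Recording` is a uniformly sampled T×C matrix plus channel metadata and
an append-only history (one record per processing step; re-running a
serialized pipeline reproduces output bitwise). Hemoglobin data are laid
out in chromophore blocks — all HbO channels, then all HbR — and HbT,
when present, is always recomputed as HbO + HbR after any step that
touches the data (checked to 1e−9). Channel ids are 1-based everywhere
user-facing, matching community convention. SNIRF files with nonuniform
time vectors (relative jitter > 1e−6) are rejected rather than resampled
silently, because implicit resampling would corrupt downstream spectral
estimates. MNI coordinates are accepted as an input table; optode
registration itself is out of scope.

## Modified Beer–Lambert law

Optical density is decadic, OD = −log₁₀(I/I₀), with I₀ defaulting to the
temporal mean per wavelength (the common convention; any window can be
supplied). Concentration changes are obtained by inverting the 2×2 system
ΔOD(λ) = d·DPF(λ)·ε(λ,·)·ΔHb per sample. The packaged extinction table is
the standard compiled hemoglobin spectrum (Prahl/Cope values, converted to
mm⁻¹·mM⁻¹) with nearest-nm lookup; DPF defaults to 6.0 at both
wavelengths and the source–detector separation to 30 mm. All three are
configurable — concentration *scale* therefore depends on these choices,
but every downstream statistic (correlations, z-maps, t-values) is
scale-invariant. Only the two-wavelength determined system is
implemented; overdetermined (>2 λ) least-squares inversion is a
documented extension point.

## Preprocessing

Stages are pure functions Recording → Recording, composable in any order
through `PipelineSpec`; every stage requires NaN-free input, and missing
samples must be linearly interpolated (`interpolate_missing`) or the
channel dropped — an explicit, logged decision.

- **Detrending** fits a polynomial (default order 1) by least squares on
  a time axis normalized to [−1, 1] for conditioning; the intercept is
  included, so output channels have exactly zero mean.
- **CBSI** forms α = sd(HbO)/sd(HbR), HbO′ = (HbO − α·HbR)/2,
  HbR′ = −HbO′/α per channel. By construction corr(HbO′, HbR′) = −1 and a
  common-mode artifact (HbO = HbR) is annihilated; channels with zero HbR
  variance are skipped with a warning.
- **TDDR** splits each channel at 0.5 Hz (skipped when fs ≤ 1 Hz, since
  the split is then undefined), robustly reweights the low-frequency
  temporal derivative with Tukey's biweight (tuning constant 4.685 on the
  1.4826·MAD scale, iterated to weight change < 1e−10 or 50 iterations),
  reintegrates, and restores the mean and high-frequency part. The
  implementation agrees with the published reference algorithm to
  r > 0.995 on motion-heavy fixtures (cross-checked against MNE's copy of
  the original in the test suite). A caveat verified by the tests: TDDR is
  near-transparent for oscillation-dominated signals but measurably
  shrinks Gaussian band-limited fluctuations (their derivative tails are
  down-weighted), so "clean pass-through" holds for oscillatory, not
  arbitrary, signals. This is a property of the algorithm, not of this
  implementation.
- **Filtering.** The Butterworth IIR (default 3rd order) is applied
  forward–backward; zero phase matters for connectivity and ALFF, and the
  effective magnitude response is |H|², which is documented rather than
  hidden. The Hamming-window FIR (default order 34, i.e. 35 symmetric
  taps) is applied single-pass with order/2-sample group-delay
  compensation (edge-padded). The FFT-ideal filter zeroes every
  conjugate-symmetric bin strictly outside the passband; DC is removed
  for band-/high-pass and kept for low-pass, with a `keep_dc` option to
  re-add the mean.
- **Nuisance regression** regresses each long channel on an intercept
  plus short-separation-channel series and/or external regressors by OLS,
  returning residual + intercept; collinear regressor columns are dropped
  with a warning and per-channel R² is logged in the history.
- **Resampling** is polyphase (anti-aliased) at the rational factor
  closest to new_fs/fs, with T′ = round(T·new_fs/fs); upsampling beyond
  100× is refused. Task onsets are stored in seconds and unaffected.
- **Custom steps** are callables (data, fs, params) → same-shape data,
  registered by name, logged like built-ins, and rejected at apply time if
  they change the shape.

## Resting-state indices

The amplitude spectrum follows the finite Fourier-series convention:
Aₖ = 2|Xₖ|/N for interior bins (|Xₖ|/N at Nyquist for even N),
a₀ = signal mean, phases such that each bin contributes
Aₖcos(2πfₖt − φₖ); Parseval's identity is enforced to 1e−6 in tests.
ALFF averages Aₖ over bins with f_lo ≤ fₖ ≤ f_hi **inclusive** (default
0.01–0.08 Hz); fALFF divides the in-band sum by the total over all
non-DC bins and therefore lies in [0, 1]. fALFF must be computed on
wide-band data: on band-passed input the denominator collapses to the
numerator and fALFF → 1 (documented, not silently prevented). The z-maps
subtract the cross-channel mean and divide by the **population**
(divide-by-C) standard deviation, which keeps the two-channel case
exactly {−1, +1}; all-identical channels make the z-map undefined and
raise.

Functional connectivity is Pearson correlation of channel series; ROI
series are the **unweighted mean** of member channels before correlation
(pairwise-correlation averaging is the obvious alternative; series
averaging was chosen and is stated here so users can judge). Fisher
z = arctanh(r) is available and recommended before group-level tests.
Zero-variance channels yield NaN correlations with a warning. Absolute
thresholding keeps off-diagonal entries strictly greater than τ; sparsity
thresholding keeps the ⌊s·C(C−1)/2⌋ largest upper-triangle entries,
keeping whole tie-groups at the cutoff and reporting the attained
sparsity. Thresholded matrices export as plain-text square matrices for
graph-metric toolkits; graph metrics themselves are deliberately out of
scope.

## Task GLM

The canonical HRF is the standard double-gamma
h(t) = g(t;6,1) − g(t;16,1)/6 (gamma densities; peak ≈ 5 s, undershoot
≈ 15 s), sampled at the acquisition rate over 32 s and peak-normalized.
Condition regressors are unit boxcars over [onset, onset+duration) —
single-sample impulses at duration 0 — convolved with h and truncated;
onsets are rounded to the nearest sample (no microtime upsampling).
Covariates are z-scored; the constant column is last. Estimation is plain
channelwise OLS with t = c'β̂/√(σ̂²·c'(X'X)⁻¹c); rank-deficient designs
fall back to the pseudoinverse with rank-adjusted dof and a warning.

No prewhitening or temporal-derivative regressors are used. fNIRS noise
is serially correlated, so single-subject t-values are optimistic; the
package treats individual-level contrasts as inputs to group-level
inference (where between-subject variance dominates), and individual
inferential statistics are intentionally not offered. AR modeling is the
natural extension.

## Group statistics

All models are channelwise general linear models on a subjects×channels
matrix: one-sample (vs μ₀), two-sample, paired (as one-sample on
differences), correlation with an external variable, one-way independent
ANOVA, one-way repeated-measures ANOVA (no sphericity correction;
Greenhouse–Geisser is an extension), and plain averaging. Centered
covariates are partialled out. Tests are two-sided by default. NaNs are
handled channelwise with per-channel degrees of freedom. Corrections
operate within an optional mask of m channels: Bonferroni flags
p ≤ q/m; Benjamini–Hochberg flags all p ≤ p₍k*₎ with
k* = max{k : p₍ₖ₎ ≤ kq/m}. Both are implemented from their definitions
and cross-checked against statsmodels in the tests. When HbO and HbR are
both analyzed, correction is applied per chromophore.

## Synthetic scenarios

The generator composes: polynomial drift; fixed-frequency oscillators
with per-channel random phases (defaults emulate Mayer waves ≈ 0.1 Hz,
respiration ≈ 0.3 Hz, cardiac ≈ 1 Hz); band-limited Gaussian "neural"
fluctuations (default band 0.01–0.08 Hz) with an optional true
inter-channel covariance; white sensor noise; Gaussian-profile motion
spikes (~0.5 s) and baseline steps entering HbO and HbR with the *same*
sign and channel-specific gains; a low-pass superficial component shared
across channels (weight 1 on short channels); and HRF-convolved task
responses with known betas. HbR is −1/3 times the neural+task HbO
component plus independent noise — encoding the physiological
anticorrelation that CBSI assumes, so motion-correction tests are
meaningful. Everything derives from one integer seed; identical spec and
seed give bitwise-identical recordings.

Named scenarios fix the study conditions used throughout tests and the
acceptance script: `rest44` (44 channels on two 3×5 probe grids — 8
sources, 7 detectors, 22 adjacent-pair channels each — 7 min at 10 Hz,
9 subjects), `task_finger` (same montage, nine subjects, 20 s tapping
blocks alternating with 20 s rest, β = 0.6 on channels 1–10),
`motion_heavy` (large spikes and steps on an oscillation-dominated
background), and `short_channel` (channels 21–22 are short-separation
references carrying the scalp component).

What passing these tests shows: the algorithms implement their stated
definitions exactly, recover injected ground truth, and are calibrated
under their own assumptions (white noise for GLM nulls, Gaussianity for
group tests). What they do not show: robustness to real-data features the
generator omits — serially correlated and heteroscedastic noise,
optode-coupling drift, nonstationary physiology, inter-subject montage
variation, and true optical partial-volume effects.

## Numerical conventions

Polynomial fits use a [−1, 1]-normalized time axis; correlations are
clipped to [−1, 1] after round-off; effectively-constant series (sd below
1e−12 of scale) are treated as zero-variance; fALFF of a zero-amplitude
channel is reported missing rather than 0/0; batch runs write
timestamp-free logs so repeated runs are byte-identical. Problem sizes in
tests (e.g. 4000 simulated null channels for GLM calibration, 200
random p-vectors for correction cross-checks) were chosen to make the
Monte-Carlo error small relative to the tested tolerances.
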