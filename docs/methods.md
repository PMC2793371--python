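# Methods

This note documents the models implemented in `eegbold`, the synthetic-data
generator that exercises them, the numerical choices, and what the passing
tests do and do not establish.

## Analysis pipeline

**Scalp projection.** Electrode rows are mean-centered over time before the
SVD, so the reported `variance_explained = s₁²/Σsᵢ²` is a true variance
fraction; the eigenvector sign is fixed by making its largest-magnitude
loading positive (the SVD sign is arbitrary and a deterministic rule is
required for bit-reproducibility).

**Morlet decomposition.** `P(f,t) = |G(f,·) ∗ ỹ|²` with the unit-energy
normalisation `A = (σ_t√π)^(−1/2)`, wavelet factor `R = 7`, on a 1–40 Hz
grid in 1 Hz steps (40 frequencies). Convolution is zero-padded; samples
within 3σ_t(f) of either boundary are flagged per frequency and excluded
from interior time-averages but retained in regressors, where the subsequent
HRF convolution and high-pass filter dominate any edge bias. Note that the
unit-energy normalisation makes the power of a fixed-amplitude tone at the
wavelet's own centre frequency scale as σ_t ∝ 1/f (verified against a
direct-convolution oracle: equal-amplitude tones at 5 and 20 Hz produce a
4:1 interior power ratio). This 1/f weighting is shared by all band-power
features and is irrelevant to the normalised spectral moments.

**Transfer functions.** TP, FR (band sums), RMSF, uRMSF, MSF, MF and GFP as
in the README. The frequency variable in the spectral moments is the grid
value in hertz, not an index. Zero-total-power columns of the normalised
spectrum are mapped to the uniform distribution with a warning; they cannot
occur once broadband noise is present. Band presets: FR3 = [1,7], [8,15],
[15,40] Hz (the upper band's printed lower edge of 5 Hz is treated as a typo
for 15; the single-bin overlap at 15 Hz is retained — it is also what keeps
TP outside the exact linear span of the three bands, so the shared
TP + FR3 design stays full rank). FR5 assigns shared endpoints to the lower
band ([1,4], [5,8], [9,13], [14,30], [31,40]); FR8 is eight 5 Hz bands. All
bands are configurable. GFP uses the RMS convention (divide by n_e inside
the root); the un-normalised variant differs only by the constant √n_e and
cannot change any GLM statistic.

**HRF basis.** Canonical double-gamma (response delay 6 s, undershoot delay
16 s, dispersions 1, undershoot ratio 1/6, 32 s support; peak ≈ 5 s), with
the temporal derivative defined by a 1 s onset-shift finite difference and
the dispersion derivative by a 1% dispersion perturbation. Both derivatives
are orthogonalised against the canonical kernel so the canonical coefficient
keeps its interpretation; F-tests over the triplet are invariant to this
choice.

**Convolution and downsampling.** Regressors are convolved causally at the
feature rate and read out at mid-TR acquisition times `(k + ½)·TR` (the
natural reference for slice-time-corrected data). The feature series is
extended backwards with its initial value for one kernel length: EEG
features are ongoing signals, and a zero pre-session state would fabricate
a session-onset response (with this choice a constant input maps exactly to
a constant, hence to zero after centering).

**High-pass filter.** Residual-forming projection onto the complement of the
discrete-cosine set containing all components with period > 128 s, applied
per session and identically to the data and the design columns of interest
(confounds enter unfiltered; the session mean absorbs offsets). The residual
degrees of freedom subtract the filter components not already spanned by the
design, which is what keeps the null F-test calibrated.

**GLM and contrasts.** Ordinary least squares per voxel; extra-sum-of-squares
F computed in contrast form `(Cβ̂)ᵀ[C(XᵀX)⁻¹Cᵀ]⁻¹(Cβ̂)/q ÷ MSE`, verified to
1e-8 against explicit reduced-model refits. Rank-deficient designs fall back
to an explicit reduced refit with rank-adjusted numerator df, since
column-selection contrasts need not be estimable there. Serial correlation is
handled by OLS with nominal df by default (the simulated AR(1) is mild and
all comparisons are relative); a pooled-ρ AR(1) prewhitening flag is
available. Family-wise error control is Bonferroni across voxels —
deliberately more conservative than random-field corrections, which are out
of scope. "Most significant maximum" ties break to the lowest voxel index.

**Activation mask.** The only analysis using stimulus-timing regressors:
per-condition boxcars, triplet-expanded, F-tested and Bonferroni-thresholded.
Comparisons report within-mask and outside-mask counts, the outside region
being the complement of the mask within the analysed voxel set.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes.

* **Protocol**: alternating 15.3 s task/rest blocks (5 scans of TR = 3.06 s
  each); task flicker frequencies drawn from
  {2, 3.75, 5, 6, 7.5, 10, 15, 30} Hz by tiling the set and shuffling, so
  conditions stay balanced. EEG at 250 Hz — enough headroom for the 60 Hz
  response of the 30 Hz condition.
* **EEG**: during a task block at flicker f, a sinusoid at 2f (the reversal
  frequency) with amplitude from a piecewise-linear inverted-U curve peaking
  at 7.5 Hz (1.5 → 5.0 → 0.3 µV from 2 to 30 Hz) — the entrainment amplitude
  falls off sharply above 15 Hz. A 10 Hz alpha component switches from
  20 µV² at rest to 8 µV² during task (desynchronisation). Both are projected
  through a single unit-norm posterior-weighted topography; 1/f-shaped noise
  (exponent 1, sd 0.5 µV) is added independently per channel.
* **BOLD**: the chosen ground-truth law applied to the simulated EEG
  features, convolved with the canonical HRF only, sampled mid-TR,
  z-scored (`standardize_regressor=True`, so `coupling_gain` is an effect
  size in noise-sd units), scaled by the gain and added to the active
  voxels; every voxel receives stationary AR(1) noise (ρ = 0.3, sd 1) and a
  random second-order polynomial drift that the 128 s high-pass removes.
  Multi-band ground truths (FR models) combine their standardised band
  regressors with fixed alternating weights `(−1)^{j+1}(1 + j/2)` so the
  generated response is genuinely frequency-dependent. Noise, drift and
  motion draws do not depend on the gain, so runs differing only in gain
  share a noise realisation.
* **Seeds**: one master seed expands into named substreams (`block-order`,
  `eeg-noise`, `bold-noise`) so components can be varied independently;
  identical parameters and seed give byte-identical outputs.

**Calibration of the defaults.** Absolute EEG/BOLD signal-to-noise is a free
parameter of the study; the defaults were fixed once at the package's desk
scale (300 scans, 200 voxels, 10% active) to give clear model recovery, and
then documented: with channel noise at 0.5 µV the first spatial component
carries ≈ 70% of the EEG variance and is posterior-loaded, total power
correlates *negatively* with the task (alpha desynchronisation outweighs the
entrainment power) while the spectral-moment features correlate positively —
the qualitative regime reported for real recordings. `coupling_gain = 3`
(three noise standard deviations) then yields near-certain recovery of
whichever law generated the data.

**What the generator does not emulate.** MR gradient and ballistocardiogram
artefacts (their removal is out of scope), realistic lead fields (the
topography is one abstract loading vector; noise is spatially white, which
makes the first-component variance fraction an *under*-estimate relative to
real data with spatially correlated background), eye blinks (the Fp1/Fp2
exclusion is exposed as an optional channel-exclusion list, not a detector),
luminance variation, and spatial voxel structure (voxels are exchangeable;
no smoothing, registration or cluster geometry). Consequently the passing
recovery tests show that the *comparison machinery* identifies the true
coupling under the assumed signal structure — they cannot show that any
particular law describes real neurovascular coupling.

## Study procedures and problem sizes

`experiments.recovery_experiment` runs 10 seeded replicates per candidate
generator (TP, FR3, RMSF): each replicate simulates one 300-scan EEG session
(30 task blocks), generates BOLD under each law in turn, derives the
activation mask, and runs the shared three-way comparison; recovery means
the generator ranks first by within-mask maximal F. The recovery criterion
(≥ 9/10 per generator) passes at 10/10 for all three at the default SNR.
`experiments.null_false_positive_rate` fits the same three-way design to
2000 voxels of pure white noise (no coupling, drift or autocorrelation) and
checks the uncorrected α = 0.05 rejection rate against the exact binomial
95% interval. These sizes keep the whole acceptance run around one minute
on a single CPU while leaving the statistical checks well-powered.

## Known limitations

* Separate-vs-shared F ordering is a strong tendency of correlated
  regressor sets, not an algebraic theorem (numerators shrink but the full
  model's MSE also shrinks); it is asserted on synthetic data with margin.
* The SSVER epoching averages overlapping windows when the reversal period
  is shorter than the window; phase-locked components are unaffected but the
  noise-suppression rate is then slightly below 1/N.
* Fixed-effects only: sessions are concatenated with session-specific
  confounds, exactly as a nine-session fixed-effects analysis; no
  random-effects machinery is provided.
* The paper-scale result this package parallels — the Heuristic uniquely
  explaining BOLD variance in real recordings — depends on the subjects'
  data and is *not* reproduced here; the package establishes the symmetric,
  falsifiable counterpart (each candidate law is recovered when true).
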