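# Methods

`mreeg` evaluates how well the standard MR artifact-reduction toolchain for
EEG recorded during fMRI — average artifact subtraction (AAS), the optimal
basis set (OBS), and carbon-wire-loop (CWL) regression — recovers known
neural signals. Because real simultaneous EEG–fMRI recordings come without
ground truth, the package pairs the correction algorithms with a synthetic
session generator whose decomposition into neural signal, artifact
components and sensor noise is exact, and with a hierarchical Bayesian
comparison layer that mirrors how such evaluations are analyzed.

## Synthetic sessions

A session is a channels × samples matrix in microvolts: `n_scalp` scalp
channels (default 32) on a parametric 2-D grid, six carbon-wire loops, and
one ECG lead. The assembled data decompose bitwise as
`neural + imaging + bcg + pump + motion + noise`; every term is kept in the
`GroundTruth` container so correction error can be measured directly
against the clean signal.

**Imaging (gradient) artifact.** A deterministic comb of cosines at
`k·f_slice ± m·f_volume` (defaults: 8 slice × 8 volume harmonics,
`f_slice = 16/1.1 Hz`, `f_volume = 1/1.1 Hz`, TR = 1.1 s), scaled to a
20 mV peak — three orders of magnitude above the physiology. All generated
frequencies are multiples of the volume frequency, so the waveform is
exactly TR-periodic (sample-for-sample when `fs·TR` is an integer), which
is what makes sliding-template subtraction effective.

**Ballistocardiogram (BCG).** Two smooth beat templates (sums of
Gaussian-windowed 3–10 Hz oscillations, support ≤ 0.65 s), each with its own
scalp topography, placed 0.21 s after every R-peak with per-beat lognormal
amplitude jitter (CV 0.05) and latency jitter (SD 2 ms). Defaults give a
250 µV peak on a unit-weight channel with ≥ 90 % of power below 25 Hz. The
template deliberately contains 9–10 Hz components: the artifact's overlap
with the alpha band is precisely what makes it harmful to resting-state
analyses, and per-channel lognormal gain modulation (SD 0.2 in log units)
keeps it from cancelling under average re-referencing. Inter-beat intervals
are i.i.d. truncated normal (floor 300 ms) around a configurable heart
rate.

**Helium-pump artifact.** Narrowband (~0.5 Hz bandwidth) harmonics of a
42 Hz fundamental, 30 µV. The harmonics are noise-driven rather than
phase-coherent tones — mechanical vibration is not phase-locked over a
session, and a coherent tone would stack at rank 2 across heartbeat epochs
and be (unrealistically) absorbed by OBS.

**Motion bursts.** Band-limited (1–25 Hz) Hann-windowed bursts during
finger-tapping blocks only, coupled into scalp and loop channels, emulating
tapping-locked vibration.

**Loops and ECG.** Each loop is a lag-shifted (±10 ms) weighted mixture of
the artifact *source* series plus 1 µV white sensor noise and no neural
component. The ECG lead carries a biphasic QRS train (600 µV) plus a small
T-wave, with a weak (5 %) imaging-artifact coupling.

**Neural signal.** Independent 1/f background noise (3 µV RMS) per channel
plus task-locked components: occipital alpha whose RMS alternates between
eyes-open (1 µV) and eyes-closed (3 µV) blocks; left-central mu-alpha/beta
suppressed by configurable ERD depths during 3-s tapping blocks with a
gamma (70–80 Hz) burst in the first second; and a biphasic visual evoked
potential kernel (P1 +5 µV at 120 ms, N1 −6 µV at 175 ms) at checkerboard
onsets with a topography contralateral to the stimulated hemifield.

What the generator does *not* emulate: volume conduction from dipole
sources (topographies are Gaussian blobs, not lead fields), respiration
artifacts, electrode pops, marker clock drift, and non-stationary artifact
morphology beyond beat jitter. Tests that pass on these sessions therefore
certify the algorithms and pipeline logic, not performance on any
particular real dataset.

## Correction algorithms

**AAS** (imaging-artifact reduction, and one of the BCG stages): for each
anchor (volume marker or delayed R-peak) the template is the channel-wise
mean over the `n_windows` nearest full epochs — a centered sliding window,
truncated at the recording edges — subtracted over the samples that anchor
owns. Defaults follow the toolbox settings: 25 windows for imaging
artifacts, 21 for BCG. Where epochs of neighbouring anchors overlap
(variable RR intervals), ownership is split at the midpoint between
anchors. On an exactly periodic artifact with exact anchors the residual
is at numerical zero.

**OBS**: per channel, the R-peak-aligned epochs (constant span, default
−0.25 s…+0.65 s around the delayed R-peak) are stacked; the epoch mean and
the first K = 3 principal components form a basis fitted jointly to every
epoch by least squares and subtracted. Joint fitting makes the residual
orthogonal to the whole basis (the normal equations); with K = 0 the fit
degenerates to a scaled mean template. If the epoch matrix is rank
deficient the component count is reduced with a warning. Two behaviours
are inherent and tested as such: the basis absorbs *any* artifact coherent
across epochs (overcorrection), and the in-sample fit removes ≈ (K+1)/N of
the variance of arbitrary signals, which only vanishes for long sessions.

**CWL regression**: the recording is cut into 4-s windows at 50 % hop with
a periodic Hann taper; per window, the tapered EEG is regressed on the
tapered loop signals shifted by every lag in ±0.021 s (single-sample grid
at the processing rate) plus an intercept, and the tapered residuals are
overlap-added with explicit weight normalization — zero regressors
reproduce the input to ~1e−15. Numerical choices: every window solve uses
the normal equations with a tiny ridge (1e−8 × the mean Gram diagonal),
because lag copies of band-limited loops are near-collinear and an
unregularized solution produces unbounded coefficients whose garbage leaks
into the taper edges; the first and last windows use flat-edged tapers so
boundary samples are fully weighted in their only covering fit. A genuine
limitation, quantified in the tests: least squares on p lagged regressors
removes ≈ p/n_eff (5–15 % at these window sizes) of *any* independent
signal's variance per window — chance-level overfitting that no
parameterization of this estimator avoids.

**R-peak detection** is a derivative-energy detector (band-pass 5–15 Hz,
squared derivative, 150 ms integration, adaptive threshold at 20 % of the
95th-percentile envelope, 300 ms refractory), with each detection refined
to the center of QRS energy; squaring makes it polarity-invariant.

**Variants.** `run_variant` composes the evaluated pipelines: NC (none),
IAR (AAS on volume markers), AAS/OBS (BCG stage after IAR, R-peaks from
the ECG unless supplied), and CWL (loop regression after IAR, with the
loops themselves imaging-artifact-reduced first).

## Signal processing and features

Downsampling is polyphase with a windowed-sinc anti-alias filter cutting
at 0.9× the new Nyquist; markers are rescaled and rounded. Low-pass
filters are odd-length Hamming-windowed sincs sized by Fred Harris'
rule-of-thumb `N = atten / (22·Δf/fs)` (30 dB, 1 Hz transition at 500 Hz
gives 683 taps) and applied by centered convolution (zero phase). Average
re-referencing subtracts the instantaneous scalp mean from scalp channels
only. Epochs are half-open sample windows; boundary events are dropped,
not padded.

PSDs use Welch's method (4096-sample Hamming segments, 50 % overlap,
density scaling) converted to dB; inputs shorter than one segment are
zero-padded (a 3000-sample trial gets 1096 samples of padding).
Multi-channel summaries always average per-channel PSDs — never the
time-domain signals, where anti-phase components would cancel — and the
averaging happens on the dB scale. Zero-power bins are floored at −300 dB.

Band powers are dB means over inclusive band edges (alpha 8–12, beta
15–25, gamma 70–80 Hz). Summary channels are selected by standardized
topography (sample SD; threshold 1 SD for resting, 2 SD for tapping and
VEP topographies), ordered by |z| with label-order tie-breaks. The evoked
response SNR is the maximum of a 20-ms sliding RMS inside the peak window
(P1 100–140 ms, N1 150–200 ms) over the mean sliding RMS of the −200–0 ms
baseline; difference waves subtract the ipsilateral from the contralateral
hemisphere mean (D1 70–100 ms, D2 130–170 ms).

## Bayesian comparison layer

Group-level comparisons use a two-level normal regression with varying
intercepts and slopes: `y ~ Normal(x·b_j, σ_method)` with participant
coefficient vectors `b_j ~ MultiNormal(β, Σ)`, `Σ` decomposed into an SD
vector (half-Cauchy(2.5) priors) and a correlation matrix Ω (LKJ(2)).
Regression coefficients get Normal(0, 10) priors. The effect-size variant
replaces the per-method residual SD with one SD per participant × method,
partially pooled on the log scale toward the method-level SD (pooling
scale half-Cauchy(2.5)); the reported within-participant effect size is
the participant average of the contra−ipsi coefficient divided by that
participant-method SD. Across-participant summaries use single-level
normal regression. Waveform similarity uses the correlation parameter of a
bivariate Student-t (means Normal(0, 100), scales half-Cauchy(2.5), ρ
uniform(−1, 1), ν ~ Gamma(2, 0.1)), which is robust to gross outliers.

All models are sampled with a package-implemented No-U-Turn Sampler:
dual-averaging step-size adaptation (target acceptance 0.85), expanding
diagonal-mass windows during warmup, divergence detection at an energy
error of 1000, default 4 chains. Hierarchical models are parameterized
non-centered; the correlation matrix uses the canonical-partial-
correlation (tanh) transform of its Cholesky factor, vectorized through
constant scatter matrices. Gradients of the production models are
hand-derived and verified, term by term, against a small reverse-mode
autodiff implementation (which also powers the centered parameterization
and serves as the independent oracle in the tests); both are checked
against finite differences. Trial-level SNR is log-transformed
before modelling and back-transformed for reporting. Convergence is
assessed with rank-normalized split R̂ (< 1.01), bulk/tail ESS (> 400) and
MCSE via ArviZ; a divergence rate above 1 % or R̂ above 1.01 flags a fit
as non-converged (the result is returned, not discarded). Posteriors are
summarized by medians with equal-tailed 66 % and 95 % intervals, and
method comparisons by the fraction of draws satisfying the contrast.

## Study orchestration and problem sizes

`run_study` simulates a cohort (participants differ by seed-driven draws
of heart rate, artifact amplitudes — BCG spread lognormal SD 0.25 — and
neural effect sizes), derives the six data variants (REF = clean signal +
sensor noise, plus NC/IAR/AAS/OBS/CWL), extracts task-matched features,
fits the models, and reports posterior summaries, adjacent pairwise
ordering probabilities, diagnostics and RMS error against the clean
signal. NC is excluded from time-domain (VEP) analyses, where the imaging
residual dominates everything.

Default study sizes are desk-scale by design: 8 participants, 250 Hz
processing rate (all analysis bands sit below the 125 Hz Nyquist; the
slice-harmonic comb tops out at ~124 Hz), 8-s resting blocks × 3 pairs,
8 tapping blocks, 6 checkerboard trials per quadrant, Welch segments of
1024 samples, and 2 chains × 500 warmup + 500 draws for in-pipeline fits.
Paper-scale counts (larger cohorts, 40-s blocks, 42 trials per condition,
5 kHz acquisition) are plain configuration changes. The resting analysis
models the per-block-pair ΔPSD (EC − EO) directly with variant as the
predictor — an equivalent contrast to the condition-by-variant interaction
design with half the parameters.

## Known limitations

* Topographies are parametric blobs; no forward model, no channel
  interpolation, no manual artifact rejection (automated thresholds only).
* The CWL chance-removal and OBS in-sample-fit effects above mean
  "no-harm" is chance-level, not zero; both are quantified in the suite.
* The NUTS implementation targets these moderate-dimension models; it has
  no dense mass matrix or within-chain parallelism.
* Acceptance-style calibration checks (interval coverage, study-seed
  replication) run at reduced sizes chosen for interactive turnaround;
  their statistical tolerances account for that.
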