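# Methods

## Timescale metrics

All metrics derive from the biased sample autocorrelation: one global mean,
full-sample variance in the denominator for every lag. This keeps
|ACF_k| ≤ 1 (Cauchy–Schwarz), makes ACF₀ exactly 1, and shrinks
high-lag estimates toward zero — preferable for short scans (T = 200)
because the unbiased per-lag estimator is wildly variable at large lags.

* **INT** sums ACF_k · dt over k = 1 … n_lag − 1, where n_lag is the first
  lag with a *strictly negative* value. If ACF₁ < 0 the sum is empty and
  INT = 0. The thresholded variants INT₀.₁ / INT₀.₅ truncate the same sum
  at the first lag at or below the threshold (that lag excluded), so they
  are exact sub-sums of INT and the ordering INT ≥ INT₀.₁ ≥ INT₀.₅ holds
  identically, not just in expectation.
* **ACW₀ / ACW₀.₁ / ACW₀.₅** are the first crossing lags, linearly
  interpolated between the bracketing integer lags; an exact hit counts as
  the crossing. One interpolation convention is used for all three
  thresholds.
* A curve that never reaches its threshold yields the full-lag-range value
  plus a `NoCrossingWarning`, never an exception: one flat ACF must not
  abort a 2,880-series cohort run. Degenerate inputs (zero variance,
  too-short series) *do* raise, because silence there would poison group
  statistics.
* **Hurst** is DFA-1: integrate the mean-removed series, split into
  non-overlapping windows at ~10 log-spaced sizes from 4 to T/4, remove a
  first-order polynomial per window, regress log RMS fluctuation on log
  window size. White noise gives 0.5 (empirically 0.51 ± 0.02 mean over 50
  seeds at T = 10,000 — the small positive bias at window size 4 is a known
  finite-size property of DFA-1); persistent correlation raises the slope.
  Series shorter than 64 points are rejected.

No band-pass filtering happens inside the metrics: filtering belongs to
fMRI preprocessing, which is out of scope here; the cohort generator
produces already-denoised-like band-limited series directly.

## Excitable-network simulator

Cyclic cellular automaton (quiescent → spike → refractory(8 ms) →
quiescent) on a **directed** Erdős–Rényi graph, edge probability
K/(N − 1). Directed edges make the branching ratio exactly σ = K·λ in the
mean-field sense; an undirected graph would give an effective (K − 1)·λ
after the first generation because the parent is refractory. Updates are
synchronous: the spike set at step t is produced by the spike set at
t − 1 (independent Bernoulli(λ) per spiking-source → quiescent-target
edge) plus external drive (probability h = 1 − e^(−r·δt) per quiescent
neuron). The spike state lasts one step; the refractory period is 8 steps
at δt = 1 ms.

Graph construction samples a binomial edge count and uniform (source,
target) pairs without self-loops, dropping duplicate pairs — an O(K/N)
perturbation of the degree, ≤ 0.1 % at the sizes used. Defaults are the
full-scale parameters (N = 100,000, K = 10, r = 10⁻⁵ per ms, T = 5050
steps, 50-step transient); sweeps and tests run the scaled size N = 10,000
with 10 trials per σ, chosen to keep a ten-point σ sweep within desk
runtime. Seeding: every run derives from
`SeedSequence([base_seed, sigma_index, trial])`, split into one topology
stream and one dynamics stream, so sweeps are reproducible and
parallelisable.

### Finite-size location of the timescale peak

At the full scale N = 100,000 trial-mean INT is maximal at the grid point
σ = 1.00, the critical-slowing-down signature. At the scaled size
N = 10,000 the measured peak sits at σ = 1.03–1.05 instead: slightly
supercritical activity there is carried by only ~10–20 simultaneously
spiking neurons, so the network repeatedly goes extinct and is re-ignited
by the weak drive (off-periods of 50–170 steps), and this slow on/off
switching lengthens the measured autocorrelation beyond the genuinely
critical point. The effect shrinks as N grows (the active pool scales with
N and re-seeding is proportionally faster). The scaled sweep therefore
shows a unimodal timescale profile whose maximum is one to two grid points
above σ = 1; this is real finite-size physics of the stated update rule,
not an estimator artifact.

## Haemodynamic bridge

Canonical double-gamma HRF (peak delay 6 s, undershoot delay 16 s, unit
dispersions, 1:6 undershoot ratio, 32-s kernel), sampled at the neuronal
step and peak-normalised. The transform is causal full-mode convolution
truncated to the input length, then decimation at t = TR, 2·TR, …, giving
exactly ⌊duration/TR⌋ samples — 150 from 300 s at TR = 2 s. No noise is
injected by default; Gaussian observation noise is available as an option.

A limitation worth stating plainly: at the scaled network sizes the
simulator's intrinsic timescales (≲ 0.2 s) lie far below TR = 2 s, so
after convolution the BOLD-domain ACF is dominated by the kernel's own
~2-s autocorrelation and the σ-dependence of BOLD-domain INT is not
statistically detectable at desk scale (measured rank correlation with the
neuronal domain ≈ 0 at N = 2,000, 150-s traces, six trials per σ).
Detecting the σ-modulation in the BOLD domain needs the full-scale network,
whose second-scale critical fluctuations survive TR sampling. The test
suite instead verifies what the transform itself must do: exact sample
counts, linearity, time-shift covariance, and preservation of timescale
*ordering* for inputs whose correlation times (0.2 / 1 / 5 s) straddle the
TR. The model recipe still computes and reports both domains.

## Synthetic cohort

Design mirrors the longitudinal study shape: 15 controls × 1 session, 15
patients × 5 sessions (~monthly), 32 ROIs in 8 networks, TR = 2 s, 210
acquired volumes minus 10 dummy volumes = 200 analysed timepoints. Each
ROI series is a stationary AR(1) process (100-sample burn-in discarded)
with coefficient φ set per (network, group, outcome, session) — chosen as
the generative family because its ACF is the closed form φᵏ, making every
metric's expected behaviour derivable and parameter recovery testable
(rank correlation between φ and estimated INT: ≈ 0.97 at T = 2,000, ≈ 0.85
at the study's T = 200).

Ground-truth structure and the reasoning behind the defaults:

* Controls: φ strictly increasing over CE < VIS < SMN < SAN < DAN < FPN <
  LN < DMN (0.15 → 0.64). The order is the *observed* control hierarchy of
  the emulated study (cerebellar shortest, default-mode longest), which
  deviates from the canonical unimodal→transmodal gradient; it is fully
  configurable.
* Patients at session 1: φ = 0.930 → 0.825 over the same order — globally
  elevated and *reversed*, so every network slows and the hierarchy
  anticorrelates with controls (recovered rho ≈ −1).
* Recovery: the session-s φ is control + (session-1 elevation) × profile(s),
  with good-outcome profile (1, .40, .32, .27, .22) and poor-outcome
  profile (1, .88, .84, .80, .76). Good recovery decays toward — never to —
  control levels; the good/poor separation is widest at session 2. The
  numerical values were calibrated by simulation so that the designed
  contrasts are detected at the study's sample sizes (n = 15 + 15, 6
  good / 9 poor): across pilot cohorts all designed effects reached
  FDR-corrected p < 0.05 in ≥ 90 % of seeds.
* Motion tables are Gaussian random walks (step SD 0.01 mm/deg), keeping
  framewise displacement (FD = Σ|Δ| of the six rigid-body parameters,
  rotations in native degrees, first frame 0) far below the 1.5 mm / 1.5°
  exclusion thresholds. The per-parameter-class QC check mirrors that
  convention; a 50-mm-sphere arc-length conversion is deliberately not
  applied.

What the generator does *not* emulate: spatial structure (voxels, lesions,
parcellation maps), scanner noise spectra, preprocessing residuals
(CompCor, band-pass ringing), inter-ROI correlation beyond an optional
shared network-level component (off by default). Passing tests therefore
demonstrate that the pipeline recovers designed temporal structure at
study-realistic sample sizes — not that real stroke data would show these
exact effect sizes.

## Statistics

Welch's unequal-variance t (Satterthwaite df, two-sided), BH-FDR within
declared families (per output table), Spearman rank correlation between
network orderings with an exact permutation p when n ≤ 8 networks (all 8!
permutations; t-approximation above), one-way repeated-measures ANOVA with
partitioned sums of squares and (k−1, (k−1)(n−1)) df, and a type-II
two-way (outcome × network) ANOVA. Choices that were genuinely open:

* No sphericity correction in the RM-ANOVA by default (the emulated
  analysis reports uncorrected-looking df, F₅,₇₀ at n = 15); the
  pingouin cross-check in the tests covers the uncorrected F.
* The six-level within design (control entered as a paired pseudo-level
  alongside the five patient sessions) reproduces those df; controls and
  patients are index-matched in the synthetic cohort, and unpaired
  patients are dropped if group sizes differ.
* Type-II sums of squares for the two-way ANOVA: robust to the mild 6-vs-9
  imbalance of the outcome groups; in the balanced case it coincides with
  type-I (tested).
* Degenerate RM-ANOVA inputs (zero error SS) return F = 0 when the factor
  SS is also zero, +∞ otherwise, rather than NaN.

## Problem sizes in the default test run

Cohort tests use the full default cohort (90 scans × 32 ROIs × 200
timepoints). Simulator acceptance checks run N = 10,000 with 10 trials per
σ over a ten-point grid; cross-domain and CLI tests use reduced networks
(N = 300–2,000) and shorter traces. The structural-recovery check runs 20
independent cohort seeds end to end.

## Known limitations

* The scaled-sweep timescale peak is finite-size shifted (see above);
  full-scale runs recover σ = 1.00.
* BOLD-domain σ-dependence is out of reach at desk scale.
* AR(1) ROI series cannot exhibit genuine multifractality or oscillatory
  structure; Hurst contrasts in the cohort reflect short-range persistence
  raising the finite-size DFA slope, not true long-memory.
* The empirical study's headline statistics (specific t, F, rho values)
  depend on restricted patient data and are not reproduction targets; the
  pipeline targets structural recovery of the findings' pattern.
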