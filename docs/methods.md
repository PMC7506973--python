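# Methods

This note documents the models, algorithms and parameter choices behind
`scrkit`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Signal model and preprocessing

Skin conductance SC(t) (µS) is treated as sudomotor nerve activity — a
*driver* d(t) with a slow tonic part and a sparse phasic part — passed
through a linear time-invariant system with a biexponential (Bateman)
impulse response h(t) = exp(−t/τ_d) − exp(−t/τ_r). Defaults
τ_r = 0.75 s, τ_d = 2.0 s follow the standard deconvolution literature
for palmar/wrist EDA; both are configurable, as is the sampled kernel's
duration (20 s, by which point the tail is below 1e-4 of its peak). The
kernel is normalised to unit area so the driver keeps conductance units
at DC, and h(0) = 0 (sampling starts exactly at the burst time).

Convolution uses a *steady-state* initial condition: the driver is
assumed to have held its initial value for one kernel length before the
recording began, so a recording that starts mid-stream has no switch-on
transient and a constant driver maps to a constant signal. The same
assumption shapes the inversion's edge handling (below).

Preprocessing is a zero-phase 5th-order Butterworth low-pass at 4 Hz
followed by convolution with a unit-sum truncated Gaussian (window 1 s,
σ = 0.2 s). Zero phase avoids distorting SCR latencies; the Gaussian
suppresses single-sample motion artifacts while leaving SCR rises
(≳ 1 s) essentially intact. When the cutoff is at or above 95% of
Nyquist — as happens at the Empatica E4's native 4 Hz EDA rate — the
low-pass stage is unrealizable and is skipped with a warning rather
than raising, so the rest of the chain still runs on low-rate
recordings.

## Deconvolution

The total driver is recovered by Tikhonov-regularised spectral
division,

    D(f) = Y(f) conj(H(f)) / (|H(f)|² + reg · max|H|²),

with default reg = 1e-4. Before the FFT the signal is padded by one
kernel length: constant (y[0]) on the left — matching the steady-state
pre-history of the forward model — and odd reflection on the right,
which linearly continues the still-decaying response; a cosine bridge
then closes the FFT buffer into a periodic signal with no cliff. With
band-limited drivers and reg → 0 the inversion is exact away from
active edges; numerically, noise-free synthetic sessions reconstruct to
RMSE ≲ 2e-7 µS at reg = 1e-8. Two caveats delimit the method's domain:

* the inversion cannot recover driver content at frequencies where
  |H|² has fallen to the regularisation floor (for the default kernel
  at 8 Hz sampling, |H|²/max ≈ 6e-6 at Nyquist), so broadband drivers
  — e.g. single-sample impulse trains — are outside its exact regime;
* driver activity within a few seconds of the recording edges is
  estimated with O(activity) error, which is why feature extraction
  trims 5 s from each segment end by default (configurable).

The tonic driver is a sliding-window 10th percentile of the total
driver (window 30 s, clamped with a warning on shorter inputs),
Gaussian-smoothed with σ = 5 s; the phasic SCR driver is the positive
part of the remainder, and the pair sums to the total exactly. Working
in driver space makes the split insensitive to constant offsets of the
signal — adding a constant moves only the tonic component, which is the
property that removes demographic baseline differences.

## Burst detection

Where an explicit count or timing of sudomotor bursts is needed, the
phasic residue (preprocessed signal minus the tonic reconstruction,
minus a smoothed 5th-percentile slow baseline that absorbs the
percentile split's small offset bias) is decomposed by sparse
nonnegative deconvolution: NNLS against a dictionary of time-shifted
copies of the template one unit-area burst produces in a preprocessed
recording (Gaussian burst → Bateman kernel → smoothing). Adjacent
nonzero coefficients within 0.7 s are clustered into bursts; clusters
below a mass threshold, or below 18% of a larger cluster within 2.5 s
(shape-mismatch remnants), are discarded. Analysis windows extend 6 s
before and 8 s after each segment so boundary bursts keep their full
response; only bursts timed inside the segment are counted. Because SCR
amplitudes vary severalfold between people, the mass threshold adapts
to the session (0.24 × the median detected burst mass, clipped to
[0.06, 0.30] µS) unless given explicitly.

## Features

The 23 per-segment features are computed on the SCR driver, in a frozen
sheet order. Definitions that the literature leaves ambiguous are
resolved as follows, and each is configurable:

* first derivative: central difference (one-sided at the edges);
  second derivative: second difference × fs²; D1, D2 are the *peak
  absolute* derivative values (the natural "maximum slope" summary),
  with D1M/D2M/D1SD/D2SD their means and sample SDs;
* IN integrates |y| (trapezoidal) — identical to the plain integral for
  the nonnegative driver but defined for tolerance-level negatives;
* SK is biased Fisher–Pearson skewness m₃/m₂^1.5, KU non-excess
  Pearson kurtosis m₄/m₂², MO the unnormalised third central moment
  (order configurable);
* F1–F3 integrate the plain (untapered) one-sided periodogram of the
  mean-removed series over half-open bands [0.1, 0.2), [0.2, 0.3),
  [0.3, 0.4) Hz; a segment must be ≥ 20 s so the resolution is
  ≤ 0.05 Hz.

Degenerate inputs (zero variance, zero area) yield NaN sentinels with a
warning; downstream analyses skip flagged cells and log the count. The
whole set is validated against an independent elementwise-loop
implementation to 1e-10 relative.

## Statistics

Features are screened for normality (Shapiro–Wilk, reported only — no
automatic switch to nonparametric tests). Each genre is compared with
the participant's neutral segment by a paired two-sided Student t-test
on per-participant differences, the two styles of a genre first
averaged within participant (an unpaired Welch variant and
"styles-as-separate-observations" are config options). No
multiple-testing correction is applied by default, mirroring common
practice of reporting raw p per cell; Benjamini–Hochberg is available.
With 23 features × 4 genres the table has 92 cells.

Under a true null the measured flag rate is slightly below the nominal
5% (≈ 4.4% over 100 null cohorts): paired differences are heavy-tailed
because participants differ in amplitude scale, which makes the t-test
mildly conservative, and the driver-minimum feature MI is almost surely
0 on both sides (clipped driver), giving p = 1 exactly.

## Classifier benchmark

SAM arousal is binarised at the scale midpoint (score ≥ 5 = high;
threshold configurable — it changes class balance). Per genre, the
dataset has one row per participant × style segment (23 raw features);
standardisation and median imputation of flagged cells use training-fold
statistics only. The catalogue is 20 fixed configurations: logistic
regression (plain maximum likelihood, no penalty), linear discriminant,
Gaussian and kernel-density naive Bayes, Gini trees with 4/20/100
splits (max_leaf_nodes = splits + 1), AdaBoosted trees, bagged trees,
RUSBoost (per-round random undersampling of the majority class,
implemented in-package), random-subspace KNN (⌈√23⌉ = 5 features per
learner), five KNNs (2/10/100 neighbours Euclidean, 10-neighbour cosine,
10-neighbour Manhattan distance-weighted), and SVMs with inhomogeneous
polynomial kernels of degree 1/2/3 (coef0 = 1) and an RBF kernel, all
capped at 10⁵ iterations with tolerance 1e-3. Ensembles use 30 learners
and boosting learning rate 0.1. KNN-100 clamps to the training-fold
size with a logged warning when the fold is smaller. Accuracy is scored
on the 15% test partition over 30 stratified 70/15/15 splits (the
validation partition is carved out but unused — no tuning is performed;
a config switch can repurpose it); splits fall back to unstratified
draws when a class is too small to stratify.

## The synthetic-session generator

Each simulated session follows the experimental schedule: a 120 s
baseline (its final 60 s exported as the "neutral" segment, so all
compared segments share one duration — several features scale with
duration) followed by the eight musical styles in randomised order,
60 s each, at 8 Hz sampling (above the E4's 4 Hz so the 0.3–0.4 Hz band
and the 4 Hz filter are well-posed; configurable down to 4 Hz).

Physiology: each window has a latent arousal a = clip(base + N(0,
0.25²), 0, 1), where base is the genre's configured level (defaults
flamenco 0.8, Spanish folklore 0.7, Cuban 0.5, rock/jazz 0.2; neutral
0). Sudomotor bursts arrive as a rate-preserving Poisson process with a
1.5 s refractory dead time, at 4 + 12a bursts/min; burst areas are
lognormal (median 0.6 µS, σ = 0.25) scaled by (0.5 + a) and by a
per-participant lognormal gain (σ = 0.5 — real EDA amplitudes vary
severalfold between people). Bursts are rendered as Gaussian bumps of
σ = 0.3 s — sudomotor bursts have finite width, and a band-limited
driver is what makes the spectral inversion well-posed; the refractory
gap keeps ground-truth bursts individually resolvable at the default
noise level, the regime in which count-recovery validation is
meaningful. The tonic driver is a per-participant level ~ U(2, 8) µS
plus a reflected Gaussian random walk (step 0.01 µS/√s). The clean
signal is the driver convolved with the Bateman kernel (steady-state
start); white sensor noise (σ = 0.01 µS) and, optionally, one-sample
spike artifacts (5–20 × noise σ) are added.

Self-report: SAM = round(1 + 8a + bias + N(0, 0.75)) clipped to [1, 9],
with a per-participant response-style bias ~ N(0, 0.75) — labels track
physiology through the shared latent arousal but are noisy, and part of
the label noise is participant-structured, as real questionnaire data
are.

What the generator does **not** emulate: overlapping/superposed SCRs
with sub-refractory spacing, non-stationary arousal within a segment,
habituation across the session, device artifacts other than isolated
spikes (electrode drift, detachment), and any acoustic structure of the
stimuli. Validation results on synthetic cohorts therefore certify the
pipeline's correctness under its own model assumptions, not performance
on any particular real recording.

Reproducibility: all randomness flows from integer seeds through
`numpy` SeedSequence spawning (per participant, per pipeline stage), so
cohorts and full pipeline runs are byte-reproducible across platforms.

## Validation-study design choices

* The deconvolution round-trip study uses random band-limited drivers
  (Gaussian bursts of σ = 0.7 s plus smoothed-noise modulation) held at
  their baseline within 40 s of the recording edges — the inversion's
  stated domain of validity.
* The exactness study runs at reg = 1e-8, the reg → 0 regime the
  property concerns; the pipeline default stays at 1e-4, which trades a
  ~0.1% reconstruction bias for noise robustness.
* The driver-recovery study (burst counts within ±10% of truth)
  disables the per-participant amplitude gain: gain is population
  heterogeneity, not signal-to-noise — a low-gain participant's small
  bursts genuinely approach the sensor-noise floor, where counting is
  ill-posed for any detector.
* The chance-level benchmark check permutes labels on a class-balanced
  subsample, because permutation preserves class imbalance and the
  40–60% chance band presumes a 50/50 prior.
* Validation cohorts use 13 participants (104 music segments) for the
  recovery study and 40 for the statistical studies, the sizes at which
  the quantities stabilise.

## Known limitations

* The spectral inversion's edge window (≈ one kernel length) is
  excluded from features but still contributes to whole-trace residual
  diagnostics on short recordings.
* Driver recovery is validated at the generator's burst separability
  regime; real recordings with dense overlapping SCRs will undercount.
* The t-test is applied to all features regardless of the normality
  screen's outcome (reported, not enforced), and several features (MA,
  MO, D1) are markedly non-normal at n = 40.
* Class imbalance in high-arousal genres inflates all benchmark
  accuracies equally; between-classifier comparisons remain meaningful
  but absolute accuracies depend on the binarisation threshold.
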