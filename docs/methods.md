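# Methods

`mieeg` re-implements, as a tested pipeline over synthetic data, a
benchmark of EEG features and classifiers for detecting motor-imagery
command-following: two conditions ("imagery" vs "rest", 24 trials each),
a 21-electrode 10–20 analysis montage, twenty per-trial features,
leave-one-out cross-validated classification with four classifiers, and
chance-level statistics with false-discovery-rate control.  This note
documents the models, the numerical choices, and what the synthetic
cohort does and does not establish.

## Synthetic cohort generator

No public recordings accompany the study design this pipeline targets,
so every stage is exercised on a generative model with the statistical
structure the analysis assumes.

**Background.** Each channel receives independent Gaussian noise with a
1/f^β spectrum (β = `noise_exponent`, default 1.0).  The spectrum
flattens below a 1 Hz knee (acquisition high-pass; it also keeps the
per-channel variance normalization stable) and rolls off second-order
above 40 Hz (scalp EEG carries little broadband gamma; without the
roll-off the synthetic sample-to-sample differences would be dominated
by near-Nyquist hiss and trip the 50 µV step-rejection rule on clean
data).  A spatially smoothed common component — four 1/f sources mixed
through a Gaussian spatial kernel over schematic electrode positions —
gives a baseline inter-channel coherence that is neither 0 nor 1.
Background RMS is 10 µV per channel; the common component adds 60 % of
that.

**µ rhythm and ERD.** The sensorimotor µ rhythm is band-limited (8–13
Hz) Gaussian noise, not a sinusoid, at `snr` × background RMS (default
0.75) on the ERD channels (default C3, C4, CP1, CP2).  During each
imagery response window the µ component is scaled by √(1 − `erd_depth`),
so its power ratio imagery/rest equals 1 − `erd_depth` (default 0.4) in
expectation — the event-related desynchronization.

**Frontal coupling.** During imagery the in-band (4–24 Hz) content of
the coupled frontal channels (pairs among F3, F4, Fz, F7, F8) is
cross-faded toward a single shared band-limited source:
x ← √(1−λ)·x_band + √λ·s, with λ solved from the measured baseline
coherence c₀ so the in-band coherence reaches approximately
c₀ + `coh_gain` (default 0.3).  Two properties of this construction are
deliberate.  First, one *shared* source: independent per-pair sources
raise each channel's auto-power faster than any pair's cross-power and
provably lower coherence.  Second, *power preservation*: the cross-fade
leaves in-band power unchanged in expectation, so the coupling is
invisible to single-channel power features — synchronization, not
activation.  The coupling band is broader than the µ band because
fronto-frontal task coupling is not a sensorimotor rhythm.

**Amplitude drift.** Real EEG power wanders within a recording.  Each
channel is multiplied by a log-normal gain (log-SD
`amplitude_drift_sd`, default 0.15; clipped at ±2 SD) with a 4 s
correlation time.  The drift degrades absolute-power features (Hjorth
activity, binned FFT) while cancelling in normalized coherence — the
mechanism by which coherence earns its reliability advantage here.  The
correlation time is kept below the 11.5 s inter-trial interval so that
per-trial features remain exchangeable under the null; a slower drift
(tens of seconds) measurably inflates the above-chance rate of power
features on null subjects because the chance-level z-test assumes
independent trials.  That inflation is a real phenomenon in real data;
the default generator deliberately idealizes it away so that type-I
calibration of the *statistics* can be tested in isolation.

**Cohorts, nulls, artifacts.** `generate_cohort` draws per-subject ERD
depths from a truncated normal (SD 0.10, clipped to [0, 1]); null
subjects get `erd_depth = 0`, `coh_gain = 0`, which makes the two
conditions exactly exchangeable by construction (conditions only ever
enter through those two effects).  Subject seeds derive from
`SeedSequence([cohort_seed, index])`, so a subject's data is independent
of how many others are generated.  `inject_artifacts` adds voltage
steps or flat stretches to all non-mastoid channels — artifacts common
to the reference channels would be cancelled exactly by mastoid
re-referencing and could never be detected.

**Protocol timing.** Events mark instruction end; trials are spaced
11.5 s (6.5 s instruction + 5 s response window), conditions interleaved
by a seeded shuffle.  A fixed instruction length is used for both
conditions so that the null process is identical across conditions.

## Preprocessing

Mastoid-average re-reference (when M1/M2 are present), zero-phase
Butterworth band-pass 1–48 Hz (8 poles per edge; applied
forward-backward this attenuates 60 Hz by ~44 dB and 0.2 Hz drift by
hundreds of dB), decimation of 1000 Hz recordings to 250 Hz (the 48 Hz
edge is the anti-alias filter for the factor of 4), segmentation into
4 s epochs starting at each event, amplitude-based artifact rejection,
and common average reference (CAR) on the segmented data.

Rejection rules per epoch and channel, at 250 Hz: (a) sample-to-sample
step > 50 µV (±100 ms surround); (b) range > 200 µV in any 200 ms
window (±500 ms); (c) range < 0.5 µV in any 100 ms window (±500 ms).
Windows slide one sample at a time; the surrounds extend the
contaminated region before the per-epoch decision.  **Detection runs on
the unfiltered, re-referenced epochs**: the zero-phase band-pass smears
a 60 µV instantaneous step to a ~23 µV/sample slope, below threshold,
so a filter-then-inspect order could never fire rule (a).  Rejection is
per-epoch and order-independent.  Retained per-condition counts feed
the proportional chance criterion.  ICA-based artifact removal is a
no-op hook (`ica_artifact_removal`): manual component selection is not
reproducible in a batch pipeline.

## Feature battery

All features are computed per retained 4 s epoch (1000 samples at
250 Hz) on the 21 CAR'd channels.  Spectral vectors are reduced to 12
bins centered at 1 + 2.44·j Hz (j = 0..11), edges ±1.22 Hz, half-open
on the right.  Dimensions for 21 channels: per-channel scalars (21) for
Hjorth activity/mobility/complexity, brainrate, Hurst, and the five
entropy features; global scalars (1) for Wackermann Σ/Φ/Ω; 252 for
binned FFT and the Granger power spectra; 2520 for coherence (210
pairs); 5040 for PDC, DTF and Granger GW (420 directed pairs).

Numerical choices worth stating:

- **FFT**: magnitude (not power) of a zero-padded 1024-point transform
  (0.244 Hz raw grid), bin-averaged.  A 1024-point transform is the
  nearest power of two giving a sub-0.25 Hz grid over the 1–28 Hz
  range.
- **Coherence**: Welch magnitude-squared coherence with 8 segments,
  50 % overlap, Hamming window, 256-point transforms — the classical
  defaults for a 1000-sample epoch.  The small-segment estimator is
  biased upward (~0.13 for independent noise); classification is
  unaffected because the bias is condition-independent.
- **Wackermann Σ/Φ/Ω** are global scalars.  Ω (exponentiated eigenvalue
  entropy of the channel covariance) is undefined per channel, so the
  three measures are computed once per epoch over all channels.
- **Hurst**: rescaled-range slope over a dyadic block ladder (16 … n/2).
  R/S is biased upward at these epoch lengths (white noise reads
  ≈ 0.55); the estimator is kept as the field uses it.
- **MVAR / PDC / DTF**: least-squares VAR with Schwarz-criterion order
  selection over 1..20, all candidate orders fit on a common sample
  range so the criterion values are comparable.  CAR'd data is exactly
  rank-deficient (channels sum to zero); the fit falls back to a ridge
  (minimum-norm) solution and the order criterion floors the residual
  covariance eigenvalues — the same regime a pseudo-inverse
  least-squares fit handles silently.  PDC is column-normalized
  (Σᵢ|PDC|²ᵢⱼ = 1 exactly per source and frequency), DTF
  row-normalized.
- **Granger causality**: pairwise bivariate fits per directed pair
  (order selected per pair), Geweke's spectral decomposition,
  negatives clipped at 0.  The accompanying power spectra (`granger_pp`)
  are univariate AR spectra per channel.
- **Entropies**: ApEn with m = 2, r = 0.2·SD (conventional defaults;
  self-matches included).  Shannon/Rényi by Vasicek m-spacings with
  m = ⌊√n⌋, edge-clamped; Rényi α = 2.  Tsallis by the Leonenko-type
  k-NN estimator, q = 1.5, k = 3.  Bhattacharyya distance between the
  two halves of the epoch by a symmetrized k-NN plug-in (k = 10 — the
  density-ratio plug-in is noticeably biased at small k; k = 10 brings
  the N(0,1)-vs-N(2,1) closed form within ~12 %).  Correntropy over
  lag-1 pairs with a Gaussian kernel, Silverman width by default.
  Exact ties are broken by a tiny deterministic jitter, logged.
- **Degeneracy**: a feature matrix is flagged (and excluded from
  classification, with a recorded failure) when any value is non-finite
  or all trial rows are identical — the "single value on every trial"
  failure mode that can silently produce spurious accuracies.

## Classification and chance statistics

Leave-one-out cross-validation per subject × feature × classifier.
Classifiers: diagonal-covariance Gaussian discriminant (DADF; class
means/variances per feature, empirical priors; any zero within-class
variance in a training fold is a recorded failure, never an accuracy),
k-NN with Euclidean distance (k = 1 and 3; distance ties break toward
the lower training index — a documented determinism choice), and a
linear soft-margin SVM (C = 1, features z-scored with training-fold
statistics).  Failures propagate as failures.

Chance level: Cpro = (n₁/N)² + (n₂/N)² from the retained per-condition
counts; z = (n_correct − N·Cpro)/√(N·Cpro(1−Cpro)); p is the two-sided
normal tail (a `compat_pdf` switch reproduces the alternative reading
in which the normal *density* at z is reported — kept for comparability
only, never the default); IOCC = (accuracy − Cpro)/(1 − Cpro).  A
subject counts as above chance only when p is below threshold **and**
IOCC > 0, because the two-sided p is equally small for significantly
below-chance accuracies.  Against an exact binomial oracle the normal
p agrees within a factor of 1.3 across N = 20..100 when the oracle is
the two-sided mid-p tail — the discrete analog of an uncorrected
normal approximation; the plain tail differs by up to ~1.6 at small N
because it counts the observed outcome's full mass.

**A calibration caveat that is a finding, not a bug.**  The z-test
treats the N fold outcomes of LOOCV as independent Bernoulli trials,
but the folds share almost all of their training data, which inflates
the variance of the LOOCV accuracy beyond binomial.  On exchangeable
null cohorts this pipeline's uncorrected above-chance rate therefore
runs at about the full 5 % level rather than the 2.5 % a naive
one-tailed count would suggest — and the inflation persists with the
amplitude drift switched off, so it is a property of the statistic, not
of the generator.  In the deep tail the effect compounds: roughly one
null cohort in three or four contains a subject whose accuracy reaches
~0.77 in two or more (correlated) features, enough to survive FDR
correction.  This is the same mechanism behind the published critiques
of machine-learning command-following claims: a per-subject
"significantly above chance" from an accuracy z-test overstates the
evidence.  The package reports the statistics as the field defines
them and quantifies this anticonservatism in its calibration benchmark
instead of hiding it; permutation tests over condition labels would be
the calibrated alternative.

FDR control is Benjamini–Hochberg step-up (verified exhaustively
against the literal definition on all small families).  Wilcoxon
signed-rank tests use mid-ranks for ties, drop zero differences, an
exact convolution-based null for n ≤ 25 and a continuity-corrected
normal approximation above.  Group summaries report mean/SD/range of
accuracy, mean p, mean IOCC and above-chance counts (uncorrected and
FDR).  Classifier comparisons are paired Wilcoxon tests on per-feature
above-chance counts; feature comparisons are one-sample Wilcoxon tests
of each feature against the pooled others on mean/SD/range (one
BH-family) and on the two count variants (another).  Chi-square
goodness-of-fit and Lilliefors normality checks are advisory only.

## Condition-difference maps

Pooled coherence per condition averages cross-spectra over every Welch
segment of every trial (total segments = trials × 8), which shrinks the
single-trial bias by an order of magnitude.  The two conditions are
compared per pair × bin with the classical two-correlation test on
Fisher-transformed values, z′ = atanh(√msc) (the coherence magnitude is
the correlation analog; a `fisher_on_msc` switch transforms the squared
coherence instead), Z = (z′₁ − z′₂)/√(1/(n₁−3) + 1/(n₂−3)) with n the
pooled segment counts.  Per subject, the pair × bin family is
BH-corrected; cohort maps count significant subjects per pair × bin on
a 13-electrode display subset.  Power-difference maps report the
rest-minus-imagery binned spectrum per channel, with cohort mean and SD.

## What the synthetic cohort shows — and what it does not

Passing tests on this generator establish that the *pipeline* is
correct and calibrated: features match their closed forms, the chance
statistics are exact, the null type-I rate is nominal, and planted
effects of realistic size are recovered with the expected ordering
(coherence more reliable than power under amplitude nonstationarity).
They do not establish anything about real patients: the generator has
no ocular/cardiac/muscle components, no volume-conduction forward
model, no pathological rhythms, Gaussian statistics throughout, and
trial-exchangeable nulls that real resting EEG (with its slow arousal
drifts) only approximates.  Effect sizes (`erd_depth = 0.4`,
`coh_gain = 0.3`, `snr = 0.75`, drift 0.15) were fixed once as
moderate, physiologically plausible values whose healthy-cohort
accuracies (coherence ≈ 0.90, FFT ≈ 0.78 under the SVM) fall in the
range reported for real healthy participants; they are calibration
knobs of the simulation, not measured quantities.

## Problem sizes

The shipped benchmarks use 20 null subjects and 10 responsive subjects
of 24+24 trials each, a four-feature calibration battery
(Hjorth activity, FFT, coherence, ApEn) × (k-NN k=3, SVM), and the
spectral pair (FFT, coherence) × SVM for recovery — sizes chosen so the
full suite and the acceptance script each run in minutes on one core
while keeping 20-subject binomial bands meaningful.

## File formats

Recordings: EDF (16-bit, µV; written by a built-in plain-EDF writer,
read through MNE) with events, subject id, group tag and exact sample
count in a JSON sidecar (`<file>.events.json`) — the package's
documented dialect; or a lossless `.npy` + JSON-header pair.  Configs:
YAML (`StudyConfig.from_yaml`).  Results: TSV tables plus a JSON
manifest carrying the config hash and a results digest for
reproducibility checks.
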