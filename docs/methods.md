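# Methods

This note documents the statistical models, the numerical choices, and
what the synthetic cohorts do and do not emulate.

## Stimulus scoring

**Intensity** is the mean target-state rating of a stimulus on the 1–9
emotional evaluation scale, reported with the sample (n−1) SD. **Hit
rate** is the fraction of raters whose target-state rating is at least
one point above *every* other state; an exact tie is a miss, which makes
the hit rule monotone in the target rating (raising a target rating can
only create hits).

**Success index.** Within a scoring pool, both the intensity means and
the hit rates are z-scored and summed. The z-scores use the
**population (N-denominator) SD**. This choice is deliberate: it is the
convention that reproduces the published validation table bundled with
the package at two decimals in all 54 cells, whereas the n−1 denominator
does not. A pool is the set of stimuli sharing one valence state within
one participant group's stimulus set (nine stimuli in the bundled
table); because the Likert-scale deposit for the larger 240-stimulus
screening is not public, the pool is an explicit argument everywhere
(`score_ratings(..., pool_by=...)`) rather than a hard-wired rule. A
pool with zero variance in either series raises
`DegeneratePoolError` — a silent 0 would corrupt rankings.

By construction the z-scores in each pool sum to zero, and so do the
success indices; tests enforce |Σ| < 1e−9.

**Selection** keeps the k highest indices per pool, breaking ties by
higher hit rate, then higher intensity mean, then lexicographic stimulus
id, so the catalog is a deterministic function of the scores.

## Group-difference tests

**Yates χ².** Hit-rate contrasts between two groups are 2×2 tables of
hit/miss counts. The statistic is the continuity-corrected
χ² = N·(max(|ad−bc|−N/2, 0))²/((a+b)(c+d)(a+c)(b+d)) with df = 1;
clamping the corrected numerator at zero (the standard convention) makes
near-null tables report exactly 0.00. The published table this package
regression-tests against prints 0.00 in exactly those rows. Uncorrected
Pearson χ² is available behind `correction=False`. Hit counts are
reconstructed from printed percentages as round(rate × n) with n = 20.
A zero margin leaves the statistic undefined and is an error.

**t-tests** (pooled, Welch, paired) delegate to `scipy.stats`; identical
paired samples return t = 0 by convention, while a constant non-zero
paired difference is an error (t would be infinite). The published
between-gender "paired" t-values are *not* asserted anywhere: the two
gender groups are independent samples, no pairing key is recorded, and
no standard formula recovers the printed values from the printed M/SD
(the pooled formula gives e.g. 3.81 where 3.71 is printed). Both kinds
are provided; the summary-statistics pooled test is what
`t_from_summary` computes.

**Normality screening** uses Shapiro–Wilk at α = 0.05; the source
analysis reports a normality check without naming the test, and
Shapiro–Wilk is the default choice at these sample sizes.

## Three-way mixed ANOVA

The design has one or two between-subject factors (age band, gender)
and one within-subject factor (emotion category); each subject
contributes one averaged value per category
(`participant_category_means`). The split-plot decomposition tests

* between effects (age, gender, age×gender) against the
  subjects-within-groups mean square, df = N_subj − (#cells);
* within effects (category and its interactions with the between
  factors) against the category×subjects-within-groups mean square,
  df = (N_subj − #cells)(k − 1).

Sums of squares come from two Type-III OLS fits with sum-to-zero
contrasts (statsmodels): the between stratum on subject means (SS
rescaled by k), the within stratum on per-subject deviations. On
balanced data this equals the classical cell-means formulas — the test
suite proves F-agreement to 1e−8 relative against an independent
brute-force oracle and against `pingouin.mixed_anova` on the
one-between-factor case — and it remains well-defined on unbalanced
complete designs (the convention of the major commercial packages). No
sphericity correction is applied by default, matching analyses that
report plain degrees of freedom. Effect sizes are partial
η² = SS_effect/(SS_effect + SS_of_that_effect's_error). Degenerate
all-equal data reports SS 0, F 0, p 1 (float-noise SS below 1e−12 of the
total is clamped to zero).

**Simple effects** compare the levels of one factor inside slices fixed
by the other factor(s), using the omnibus error term appropriate to the
effect factor (within error for the within factor, subjects error
otherwise) with the observation counts of the slice cells; p-values are
Bonferroni-adjusted within each slice's family (p·m capped at 1). Using
the omnibus error for a between factor inside a within-level slice is a
pragmatic approximation — an exact treatment would mix both error
strata — and is adequate for the planted-effect recovery the package is
designed around.

## EEG pipeline

Recordings are 14 channels (AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8,
FC6, F4, F8, AF4 — the Emotiv EPOC layout in the 10–20 system) at
256 Hz, in microvolts.

**Band-pass 0.1–50 Hz.** Implemented as an order-8 zero-phase
Butterworth low-pass at 50 Hz followed by an order-2 zero-phase
high-pass at 0.1 Hz. Two numerical points drove this design. First, a
single band-pass section spanning 0.1–50 Hz is dominated by the ~10 s
ringing of its low corner, so low-pass and high-pass are applied
separately, low-pass first: anything the high-pass stage sheds below
50 Hz would otherwise survive. Second, forward-backward padding is
scaled to each corner's time constant, and the high-pass uses
even-symmetric padding so the extension is level-continuous at the
boundaries and barely excites the slow corner. With these choices a
60 Hz line component keeps < 10% of its RMS, attenuation is ≥ 24 dB one
octave outside either corner, and the passband is flat within 1 dB.
A conventional order-4 band-pass fails the 60 Hz requirement (≈23%
residual even zero-phase), which is why the order is 8.

**Notch** at 50 Hz: zero-phase IIR notch, Q = 30 (≤ 1 dB change at
±5 Hz).

**Artifact screening** automates a manual-rejection protocol: 1-s
segments on the global grid are flagged when any sample exceeds
±100 µV or a per-channel robust z of 5 (median/MAD over the recording),
and flagged segments are excised with trial windows remapped. At most
10% of the data may be removed — a hard invariant of the report object;
if more is flagged, only the most extreme segments up to the cap are
removed and a warning is recorded. The exact thresholds stand in for
judgements no protocol document records; they are configurable.

**Epoching** slices each trial into non-overlapping 1-s epochs (exactly
fs samples), discarding the trailing partial second; epochs inherit the
trial's condition label. Trials shorter than 1 s are errors. Baseline
periods are simply not listed as trials, so no baseline normalisation is
applied.

**Differential entropy.** For a zero-mean Gaussian, DE = ½ ln(2πeσ²),
so the feature reduces to the log band variance up to constants. Band
variance is computed spectrally: the mean-removed periodogram power in
the half-open interval [low, high) (Parseval), i.e. an ideal band-limit
followed by the N-denominator variance. The spectral estimator was
chosen over per-band IIR filtering because a zero-phase Butterworth
band filter's squared magnitude keeps only ~86% of in-band variance,
biasing DE by ≈ −0.07 nats; the ideal band-limit has a flat passband,
so a band-limited unit-variance signal measures 1.4189 nats
(= ½ ln 2πe) exactly in expectation, scaling a signal by c adds ln|c|
exactly, and white noise of variance σ² carries σ²·2(high−low)/fs per
band. Zero band variance (DE → −∞) raises `DegenerateBandError` rather
than returning a sentinel.

The feature matrix is epochs × (14 channels × 5 bands) = epochs × 70,
channel-major (channel i // 5, band i % 5); the
`DifferentialEntropyExtractor` is a scikit-learn transformer over
(n_epochs, n_channels, n_samples) arrays, and the whole pipeline is
deterministic: identical input gives a bit-identical matrix.

## Classifier harness

Eleven classical classifiers with library defaults (Random Forest with
200 trees; MLP with one 64-unit hidden layer, 500 iterations; logistic
regression capped at 2000 iterations). Scale-sensitive members are
pipelined behind a `StandardScaler` fitted on training data only; tree
ensembles see raw features. The split is stratified at the epoch level
at ratio 0.8 by default; because epochs from one video are correlated,
a trial-grouped split (`groups=` / `--group-by-trial`) is provided and
will generally score lower — both modes are honest, they answer
different questions. Accuracy is plain top-1 percentage. Aggregation
over participant groups is the unweighted arithmetic mean per stimulus
source, rounded half-up to 2 dp; rounding half-up at the presentation
layer only is a package-wide convention (`round2`).

## Synthetic cohorts

**Ratings.** A rating is a clipped-and-rounded continuous latent:
grand/category mean + group shift + participant effect + stimulus
effect + noise. Default category means on the valence and arousal
scales are the published cohort-level descriptives (neutral arousal
≈ 2.2, emotional arousal ≈ 6.2), with female-minus-male shifts per
category matching the published directions — so ANOVA smoke tests show
the right qualitative pattern without claiming any cohort F value. The
emotional-evaluation triple uses a target-state latent at mean 7.2 and
per-stimulus hit gaps drawn from N(2.2, 0.5²): the per-stimulus gap is
what spreads hit rates over roughly 60–100%, giving the success index a
real ranking task. Defaults: participant SD 0.5, stimulus SD 0.3, noise
SD 0.8, n = 20 per group cell. The clip-then-round response model is
the simplest latent model that is invertible in expectation; it is not
a psychometric claim.

**EEG.** Each channel is a sum of ideally band-limited Gaussian noise
with per-condition variances (brick-wall spectral construction,
normalised to the exact configured variance, hence no filter edge
transients and an analytically known DE per band), a 1/f background,
and raised-cosine 0.3-s blink pulses on AF3/AF4 (half amplitude on
F3/F4) with Poisson timing. Default trial lengths are uniform on
91–229 s, the duration range of the validated stimulus set; tests use
shorter explicit ranges (20–100 s) to keep runtimes in seconds, a
purely computational choice since every property tested is
length-invariant. The planted condition contrast is a γ-power ratio
(default 2:1 positive:neutral), recoverable as a mean DE difference of
½ ln 2 ≈ 0.347 nats.

What the generators do **not** emulate: 8-category discrete-emotion
structure beyond additive shifts, rater response styles or scale-use
habits, EEG nonstationarity, volume conduction or any biophysical
forward model, eye movements other than blinks, and order effects
(stimuli are exchangeable within blocks). Passing tests therefore
demonstrate correctness of the *computations* under a known model, not
performance claims about real cohorts — in particular, published
absolute recognition accuracies are not reproducible without the raw
EEG, and no test asserts them.

## Problem sizes and calibration checks

The power/type-I acceptance check runs 200 seeds of a 3×2×2 design with
10 subjects per cell (Δ = 2σ within effect): detection at p < 0.001 in
≥ 95% of seeds, pooled null rejection within [0.025, 0.075] at α = 0.05.
The classifier chance check uses 500 label-shuffled epochs and a
binomial test against 1/3 at α = 0.01 per roster member. The ANOVA
oracle equivalence covers balanced designs up to 3×2×8 with 10
subjects/cell at 1e−8 relative on F.

## Known limitations

* Unbalanced designs use Type-III/sum-contrast sums of squares; the
  classical-formula equivalence is only guaranteed balanced.
* Simple-effect tests reuse omnibus error terms (see above).
* The EDF reader depends on MNE; EDF *writing* is out of scope — the
  simulators and CLI emit delimited text.
* The published between-gender "paired" t-values are documented but not
  reproducible from the printed summaries; see the t-test section.
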