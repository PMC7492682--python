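# Methods

This note documents the models, conventions and design choices behind the
pipeline, in the order the stages run.

## Synthetic cohort: what it emulates, and what it does not

The generator produces one recording per participant × movie at 60 Hz with
the signal structure the analysis assumes:

- **Gaze.** Alternating fixation plateaus and saccadic jumps. Fixation
  durations are log-normal with a median of 250 ms (shape σ = 0.4), floored
  at the detector's minimum duration (6 samples) so that every planted
  fixation is in principle detectable. Saccades last 1–3 samples with
  amplitudes drawn as `floor + Gamma(k=2, θ=35)` px (floor 50 px); the floor
  keeps every saccade above the I-DT dispersion threshold (≈ 34 px), without
  which adjacent plateaus would merge and no detector could match the
  planted event count. Within a fixation, samples jitter isotropically
  (σ = 1.5 px); saccade samples interpolate linearly between centroids.
  Jump directions are uniform, re-drawn to stay inside an 80 px screen
  margin.
- **Pupil.** `y(t) = b0 + b1·x(t) + offset + drift(t) + ε(t)` per eye,
  where `x` is the movie's luminance aligned sample-and-hold to the gaze
  clock. Participant baselines `b0 ~ U(28, 32)` device units and slopes
  `b1 ~ U(−13, −9)` device units per luminance unit bracket a typical
  printed participant model (`y_est = 29.84 − 11.23x`). The class offset is
  `z·scale` with default pattern `{C1: +0.85, C2: −0.73, C3: −0.43}`
  (mirroring the expected ordering of standardized per-class pupil means)
  plus a per-recording emotional deviation (σ = 0.5); `drift` is smooth
  noise (σ = 0.3, ~1 s correlation) and `ε` white noise (σ = 0.5).
  Pupil units are abstract device units: consumer eye trackers report
  uncalibrated diameters, so only relative structure is meaningful.
- **Blinks.** Poisson events (15/min by default) lasting 80–300 ms replace
  samples with invalid flags and NaNs. Designated high-loss participants
  blink at 130/min, which puts their pooled loss near 43% — safely above
  the 25% rejection threshold for any seed — while normal participants stay
  near 5%.
- **Movies.** Per-frame luminance is a smoothed Gaussian fluctuation around
  the movie mean (σ = 0.05 by default, 0.5 s smoothing), clipped to [0, 1].
  Frames realize that series exactly in their mean intensity and carry a
  checkerboard texture of amplitude `dynamics_level / 2` whose sign
  alternates per frame, so the mean absolute inter-frame difference equals
  `dynamics_level` whenever the luminance change between frames is smaller
  than the texture step. Default dynamics levels make the pleasant class
  (C1) markedly more dynamic than the neutral and unpleasant classes,
  echoing the qualitative pattern in real stimulus sets.

Defaults were chosen so the luminance confound is material: with the above
variances the per-participant pupil–luminance correlation lands near −0.5
before correction (seed 1 measures −0.57) and near 0 after.

What the generator does **not** model: real video content (frames are
textures, not scenes), smooth pursuit, head movement, tracker-specific
noise spectra, asymmetric eye signals, or any link between gaze position
and scene semantics. Passing tests therefore demonstrate that the pipeline
recovers structure *of the kind assumed*, not that real recordings contain
that structure.

All randomness flows from one integer seed; per-recording substreams are
spawned from (seed, participant index, movie index) and a movie's luminance
series depends on the movie identity only, so it is shared across
participants.

## Preprocessing

Order is fixed: rejection check → interpolation → filtering. Rejection is
evaluated per participant over the concatenation of all their recordings
(the rule drops a participant completely; per-movie granularity is not
offered), strictly greater than the 25% threshold. Interior gaps are filled
linearly between flanking valid samples; leading/trailing gaps extend the
nearest valid value, since two-sided interpolation is undefined there. The
Butterworth low-pass (order 4, 5 Hz cutoff) is applied forward–backward
(`filtfilt`) so fixation timing is not lagged; the two passes square the
single-pass magnitude response, which only sharpens the stop-band (a 25 Hz
tone is attenuated to ≈ 2.6 × 10⁻⁶ of its amplitude; 0.5 Hz passes within
2%).

## Event detection

- **I-DT** (default): maximal windows with x-dispersion + y-dispersion
  below threshold and length ≥ 6 samples. The threshold defaults to 1° of
  visual angle converted through the screen geometry (≈ 34 px at 60 cm on a
  1920×1080 display whose 2° neighbourhood is 68 px).
- **I-VT**: point-to-point velocity is a property of the *transition*
  between samples; a sample is fixational when at least one adjacent
  transition is below threshold (500 px/s ≈ 15°/s). This convention is
  deliberate: labelling a sample by its incoming velocity alone misassigns
  the first sample of every fixation, whereas the transition rule
  reproduces planted fixation boundaries exactly on noise-free data. The
  event-detection oracle tests therefore use I-VT for exact interval
  equality; I-DT is checked for count equality and centroid accuracy, since
  its greedy window can absorb a near-boundary saccade sample by design.

Saccade amplitude is the distance between consecutive fixation centroids
(robust to onset jitter), duration the inter-fixation gap in samples —
possibly zero, which is retained. A recording with fewer than two
fixations simply yields no saccades; feature extraction handles the
degenerate cases below.

## Features

Eighteen features per participant × movie, in a fixed documented order:
fixation count and OFV, then moment blocks (mean, variance, skewness,
kurtosis) for fixation durations, saccade amplitudes, saccade durations and
the luminance-corrected pupil trace. Only the count and the OFV are
divided by recording length; the normalization makes them invariant to
clip duration (verified by self-concatenation).

Conventions, chosen so classifiers never see missing values:

- variance uses the n−1 denominator and is 0 for samples of size < 2;
- skewness and kurtosis are the population moment ratios (`g1`,
  `g2 = m4/m2² − 3`, excess form: a normal scores 0) and are 0 for samples
  of size < 3 / < 4 or constant samples;
- the OFV is reduced to a scalar by the Euclidean norm of the duration-
  weighted offset sum (it is one feature slot; components are available via
  the underlying sum if signed structure is needed);
- z-scoring is within participant across all of that participant's
  available movies, with population (ddof = 0) scaling — two movies map to
  exactly ±1 — and zero-variance features map to 0. A single-movie
  participant is an error, as standardization is undefined.

## Luminance correction

One OLS model per participant, fitted jointly over all that participant's
movies: per-movie fits would absorb exactly the between-movie emotional
differences the analysis is after. The pupil input is the mean of both
eyes after preprocessing. Residuals on the fitting data are mean-zero and
uncorrelated with luminance by construction (asserted to 10⁻¹⁰), and the
correction is idempotent (refitting on residuals gives slope 0). Constant
luminance raises an error — the slope is unidentifiable.

Frame-to-sample alignment is sample-and-hold on the active frame (luminance
is piecewise-constant per frame; interpolation would invent intermediate
luminances). The neighbourhood variant averages the HSV value inside a
circle of 68 px (2°) around the gaze point, clipped to the frame; the
vectorized implementation rounds gaze to the frame grid and matches the
reference per-pixel mask to machine precision at integer gaze positions.

## Dynamics index

The per-transition index sums absolute per-pixel differences; the movie
summary is the mean over transitions divided by the pixel count. The
absolute value is essential — a signed sum cancels to ≈ 0 for any
luminance-stable movie — and the per-pixel normalization makes the index
resolution-independent, so only its rank/ratio structure across movies is
meaningful. The mean (rather than sum or median) over transitions is used
as the per-movie summary. Feature correlations are computed within
participant across movies and averaged over participants; a participant
with a constant feature is excluded from that feature's average with a
warning rather than contributing an undefined correlation.

## Classification and screening

LOSO folds are per participant; pooled fold predictions form the confusion
matrix (rows predicted, columns true), and the reported accuracy is the
pooled-matrix accuracy (trace/total); per-fold accuracies are retained
separately. Classifier choices where the reference design is silent:
quadratic SVM = SVC with polynomial kernel of degree 2, C = 1, γ = 1,
coef0 = 1, one-vs-one multiclass; LDA with pooled covariance (SVD solver);
kNN with k = 11, Euclidean metric, vote ties broken by the smallest summed
distance to the tied classes' neighbours (a reproducible, deterministic
rule; library defaults break ties by label order). All are config-exposed.

The feature screen reports, per feature: the minimum per-class KS p-value
against a normal with moments estimated from the sample (the exact KS
variant used in the reference analysis is unstated; estimating moments from
the data makes the test slightly conservative — a known limitation), the
one-way ANOVA F and p, a significance flag at p < 0.05, and pairwise Welch
tests with Bonferroni multiplication by 3 capped at 1.

One rounding convention worth recording: in the reference metric table the
F1 column equals the harmonic mean of the *printed* two-decimal precision
and recall, and the mean row averages the printed cells; the package
computes unrounded metrics, and the acceptance tests reproduce the printed
table by applying that convention explicitly.

## Problem sizes and determinism

The default study (30 participants × 6 movies of 5–13 s at 60 Hz, frames
at 25 fps and 120×160 px) runs end to end in a few seconds; tests and the
acceptance script use this scale, with multi-seed classification checks at
25 participants. Identical (config, seed) pairs produce byte-identical
feature tables; all stochastic tests are seeded or derandomized.

## Known limitations

- The generator's class effects are planted directly at the
  feature-generating level; recovered effect magnitudes depend on the
  within-participant variance mix and match the planted z-pattern in
  ordering more faithfully than in magnitude.
- Standardization across all available movies versus only the analysed
  class movies is a genuine ambiguity; both are supported (the default
  standardizes across whatever movies are present in the feature table).
- The PNG frame writer quantizes float frames to 8 bits and is for
  inspection only; analyses use the in-memory float frames.
- The CLI's stagewise `features` command assumes the generator's default
  25 fps for luminance CSVs; the in-memory `all` pipeline carries frame
  rates explicitly.
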