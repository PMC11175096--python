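# Methods

This note documents the models, parameter choices and numerical decisions
behind `movequal`, and what the synthetic cohorts do and do not emulate.

## Task and signal model

One wrist-worn IMU (3-axis accelerometer in m/s², 3-axis gyroscope in
rad/s, 60 Hz) records a cyclic weighted reaching task: 14 repetitions of
moving a 0.5 kg load from the side of the body to 90° humerothoracic
elevation and back, with short rests between repetitions. The analysis
uses only the Euclidean norm of the raw acceleration, so no orientation
estimation or gravity subtraction is performed; the constant gravity
offset is removed where it matters (jerk, RMS, autocorrelation) by mean
removal, which differentiation would eliminate anyway. Time is seconds
from trial start; up to 1% sampling jitter is tolerated and no resampling
is applied.

## Repetition segmentation

Non-moving samples are identified on the gyroscope norm after a 4th-order
forward–backward Butterworth low-pass at 2 Hz (zero phase; effective
magnitude = squared single-pass response; reflective padding of 3× the
filter's impulse length against edge transients). The three gyro axes are
reduced to their 2-norm before filtering — orientation-invariant and
consistent with the norm treatment of acceleration.

Detection parameters (all configurable, all recorded in the run manifest):

* **rest threshold** — 0.05 × the 95th percentile of the filtered norm.
  The percentile makes the reference robust to spikes; on noise-free
  synthetic trials any fraction in ≈ 0.03–0.2 recovers the generated
  repetition count.
* **minimum movement bout** — 0.5 s; **maximum merged gap** — 0.25 s.
  Gaps shorter than the merge threshold are treated as within-repetition
  dips (the brief pause at the plate between the up and down strokes), so
  one repetition = one up-and-back bout; merging runs before bout-length
  filtering.
* **boundary refinement** — the low-pass smears bout edges into the rests,
  so each candidate edge is snapped to the nearest crossing of an adaptive
  rest threshold on the *unfiltered* gyro norm: 3× the median raw norm
  over the detected rest samples (with a tiny floor for noise-free data).
  With zero-velocity rests this recovers the movement support exactly;
  with measurement noise it sits safely above the rest noise floor.

The raw acceleration norm over the refined segments, concatenated in
order, is the series all metrics consume (14 × ≈ 100 samples ≈ 1400
points per trial). A warning is emitted when the detected bout count
differs from the expected 14.

## State-space reconstruction

* **Dominant frequency f₀** — Welch periodogram (Hann, 50% overlap,
  segment length min(n, 4·fs/f_min) with f_min = 0.1 Hz), DC bin excluded.
  A peak-to-median power ratio below 30 triggers a "peak not well
  separated" warning: white-noise periodograms reach ratios of ~7–16,
  while the task signal's ratio is orders of magnitude larger.
* **Time lag τ** — first robust minimum of average mutual information
  (equal-width histograms, ⌈n^{1/3}⌉ bins, floor 8) over lags 1..fs/f₀.
  "Robust" means no lower AMI occurs within the next 5 lags — the plain
  first-local-minimum rule latches onto one-sample dips of the histogram
  estimate on near-deterministic signals (a noiseless sine yields lag 2–4
  instead of the quarter period). A lag is also accepted immediately once
  AMI has collapsed below 5% of its lag-0 value (memoryless signals:
  white noise correctly yields τ = 1). Fallback: a quarter of the
  dominant period.
* **Embedding dimension d** — smallest d in 2..10 whose false-nearest-
  neighbor fraction (Kennel criteria, Rtol = 15, Atol = 2) is below 5%;
  d = 10 with a warning otherwise.

## Local dynamic stability (Rosenstein λ)

Each embedded point is paired with its nearest neighbor outside a Theiler
window of one movement cycle (fs/f₀ samples); λ is the least-squares slope
of the mean log divergence ⟨ln d(k)⟩ over the fit range, × fs, reported in
nats/s with per-sample and per-cycle values derivable (λ/fs, λ/f₀). The
default fit range is 0 to half a cycle — the short-term divergence
convention of the cyclic-movement stability literature. Note that this
short-term slope is *not* an estimate of the asymptotic exponent: on the
Lorenz system the asymptotic exponent is recovered (within 10–20% of a
tangent-space Benettin computation) only when fitting the post-transient
linear region of the curve, past the initial neighbor-convergence /
noise-equilibration shoulder (~0.5 cycles); the oracle tests therefore
pass explicit fit ranges. Pairs whose divergence is zero (exactly
repeating cycles) are excluded; if fewer than 10 valid pairs remain the
metric fails — on perfectly noise-free periodic data this is a genuine
degeneracy and is reported as such.

## Sample entropy

Richman–Moorman convention: m = 2, Chebyshev distance, self-matches
excluded, both the m and m+1 counts over the first n−m templates, no
signal normalization. The tolerance r = 0.2 × SD (ddof = 1) of the
**baseline** concatenated norm is person-specific and reused verbatim for
the same subject's follow-up trial, so a follow-up change in signal
amplitude changes the entropy rather than silently rescaling the
tolerance. A = 0 yields +inf with a warning; constant baselines make the
tolerance zero and fail loudly. Sample entropy is non-increasing in r on
study-length series (n ≈ 1400) from r = 0.2 SD upward; for very small r
or short series the A/B ratio estimate can fluctuate non-monotonically —
a small-sample property of the estimator, not an implementation artifact.

## Smoothness (LDLJ, acceleration variant)

Per repetition: with T the repetition duration, a(t) the mean-removed
acceleration norm, jerk j = da/dt by central differences (one-sided at
edges), and a_peak = max |a|:

    LDLJ = −ln( (T / a_peak²) ∫ j(t)² dt )

Dimensionless: invariant to amplitude scaling and to shape-preserving time
scaling. The trial value is the mean over repetitions — concatenation
seams would inject artificial jerk spikes if LDLJ were computed on the
concatenated series (that alternative is available via
`log_dimensionless_jerk` on any segment). The standard sign convention is
used: smoother ⇒ higher (less negative). The symbolic minimum-jerk stroke
gives LDLJ = −ln(21.6) ≈ −3.073 exactly, which the implementation matches
within discretization error.

## Symmetry and variability

Symmetry: unbiased, mean-removed, variance-normalized autocorrelation,
maximized over lags in [0.5, 1.5] × fs/f₀; exact repetition gives 1; the
estimate is clipped to [−1, 1] (the unbiased normalization can
infinitesimally exceed 1). Variability: mean over all stride-1 windows of
the 10-sample RMS of the mean-removed norm.

## Cohort statistics

Wilcoxon signed-rank (two-sided; zeros dropped and counted; exact null for
n ≤ 25 without ties, otherwise normal approximation with tie and
continuity corrections — empirical size 0.048 at n = 30, within the
±0.015 calibration band), Spearman mid-rank correlations with t-
approximation p-values, strength bands on |r_s| with left-closed edges
(0.25 is "fair"). Degenerate cases (all-zero differences; zero rank
variance) are flagged, not raised, at the cohort level. Normality is
screened descriptively (Shapiro–Wilk, skewness, kurtosis) for reporting
only — the analysis is fixed as non-parametric and never switches tests.
No multiplicity adjustment by default; Holm step-down is available per
analysis family for reuse beyond the two-timepoint design.

Per-metric failures are isolated per subject (a degenerate Lyapunov
computation does not void that subject's entropy), and subjects enter
each test pairwise-complete. Eligibility mirrors the cohort's inclusion
rule: baseline Quick DASH ≥ 15 flags the subject excluded.

## Synthetic cohorts

The generator emulates the study conditions: 30 subjects × 2 timepoints,
14 repetitions at 60 Hz, 5/3 s per repetition (≈ 100 samples, fixing the
≈ 1400 analysed points), 1 s rests; a minimum-jerk up-and-back stroke pair
as the clean movement kernel (closed-form, analytically known LDLJ);
gravity fixed on one sensor axis with the movement acceleration mostly
along it, so the norm's gravity cross-term varies linearly with the
movement at the repetition frequency (0.6 Hz). Sampling within a
repetition is cell-centred, so every movement sample has strictly nonzero
angular velocity and the segmentation ground truth is exact. Measurement
noise (default 1% of movement amplitude) is added to the accelerometer;
the gyroscope is left noise-free so rests carry exactly zero angular
velocity and the rest/movement ground truth stays unambiguous.

Four degradation knobs each drive one metric, verified monotone over ≥ 20
seeds: per-repetition amplitude jitter (entropy, variability), a
multiplicative 6 Hz modulation of the movement acceleration (smoothness —
additive mid-stroke ripple was rejected because it inflates a_peak as much
as the jerk integral and barely moves LDLJ), alternate-repetition scaling
(symmetry), and smooth band-limited waveform perturbations (stability).
`effects` shifts the knobs between baseline and follow-up; an empty map
makes the two timepoints exchangeable (verified by KS screening over null
cohorts).

PROM scores use the cohort's published moments — Quick DASH 3.35 ± 4.36
(pre, truncated below 15 by rejection sampling under the inclusion rule)
and 18.59 ± 17.44 (post); pain item 1.1 ± 0.3 (pre) and 1.9 ± 1.0 (post)
as a latent normal rounded into 1..5. `clip_mode="none"` returns the
latent draws so moment recovery can be tested; `"clip"` applies the
instrument ranges. The pain mechanism is a stand-in, not an ordinal model
of the instrument.

Not emulated: realistic shoulder kinematics and orientation dynamics,
sensor bias/drift/saturation, pain- or lymphedema-driven movement changes,
between-subject heterogeneity of pacing. Passing tests therefore show the
*pipeline* is correct and calibrated under the stated signal model, not
that the metrics discriminate clinical status in real recordings.

## Problem sizes and determinism

All randomness flows from root seeds through `numpy` SeedSequence
spawning; identical config + seed gives byte-identical cohorts. Simulation
sizes were chosen to keep the default suite fast while leaving the checks
well-powered: 2,000 null cohorts for type-I calibration, 25 cohorts of 30
subjects for the smoothness-shift power check (>80% required; the
injected effect is ~10 per-subject SDs, so power is effectively limited
only by cohort count), 60 cohorts for the exchangeability KS screen using
the two embedding-free metrics, 20 seeds per degradation-monotonicity
check, and 10 noise seeds for profile repeatability.

## Known limitations

* The smoothness literature disagrees on the sign convention; this package
  defaults to the standard one (smoother = higher LDLJ) and offers
  `negate_ldlj` in `compute_profile` for conventions that read a high
  value as unsmooth, plus `ldlj_on_concatenated` to compute smoothness on
  the whole concatenated series despite its seam artifacts.
* The short-term λ depends on the fit range and Theiler window; values are
  comparable only across runs with identical reconstruction parameters
  (all recorded per subject in the manifest).
* Sample entropy at n ≈ 1400 with m = 2 is stable but not asymptotic;
  comparisons must hold n fixed, which the fixed task protocol does.
* The segmentation assumes rests genuinely quieter than movement by an
  order of magnitude on the gyro norm; tasks without clear rests need the
  threshold fractions retuned.
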