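# Methods

## Generative model

Each stimulus category c ∈ {face, place, body, object} drives a fixed
sequence of processing *stages* s, each with its own sensor topography
a_{c,s} and temporal kernel k_s(τ) of the post-onset lag τ. The sensor
signal of a stream trial is the linear superposition

x(t) = Σ_i Σ_s g_{i,s} · a_{c_i, s} · k_s(t − onset_i) + ε(t),

with i running over stream positions 1..12 (T1 at position 0 is a color
patch: a pure timing anchor with no category signal), g_{i,s} the
attentional gain of stimulus i at stage s, and ε i.i.d. Gaussian sensor
noise. Linearity is exact by construction and is verified to machine
precision by the test suite.

**Topographies.** Unit-norm random vectors with pairwise |cosine| < 0.3
(sequential rejection sampling, 1000 attempts per slot, deterministic given
the seed). The bound mimics the partial overlap of real category maps; it
also means cross-stage generalization is damped but not exactly zero — an
early-trained classifier picks up a small, label-correlated share of the
late response, just as biphasic classifier timecourses show in real
recordings. The exact-orthogonality regime (where the kernel-overlap oracle
is sharp) is exercised separately in the tests with QR-orthonormalized maps.

**Kernels.** Four stages on a 0–900 ms lag axis, each zero outside its
window ± a 50 ms skirt, non-negative, continuous-time maximum 1
(on the sampled grid the maximum can fall marginally below 1 when the
window midpoint is off-grid):

| stage   | window (ms) | shape                              | role |
|---------|-------------|------------------------------------|------|
| early   | 90–230      | truncated-Gaussian bump (peak at the midpoint, sd = (halfwidth+skirt)/3) | feedforward transient |
| mid     | 220–330     | truncated-Gaussian bump            | intermediate stage |
| late    | 350–720     | plateau with 50 ms raised-cosine ramps | task-related sustained stage |
| sustain | 440–720     | plateau with raised-cosine ramps; re-uses the *early* topography | attention-gated maintenance of the early code |

The sustain stage carries the gradual-selection hypothesis: amplifying it
prolongs the early-stage code without touching the first transient,
matching the observation that first peaks are equal across conditions while
the sustained phases differ. Whether target amplification should instead
scale the transient is left open by the timecourse evidence; scaling the
sustain is the only choice consistent with equal first peaks, so it is the
default and the only implemented attachment.

**Selection models.** In *gradual* mode the sustain gain of position i is
`amplitude · exp(−d²/2σ_side²)` with d = i − target; σ_left = 1.2 positions
and σ_right = 0.25·σ_left (asymmetric toward preceding positions — the
stimuli already buffered when the cue arrives), amplitude 2. The late stage
is silent: selection is entirely graded. In *discrete* mode the sustain is
silent and the late-stage gain is `2 · (1.0, 0.7, 0.4)[guess rank]` for
reported stimuli and exactly 0 otherwise: selection is all-or-none and
report-linked. Behavior is sampled first (so the discrete gains can be
conditioned on the sampled guesses), from a distribution over positions
1..12 that mixes an attention component (discretized Gaussian of width 1.2
positions in gradual mode; a point mass in discrete mode) with a uniform
guessing floor (0.25); guesses are drawn without replacement. A per-lag
multiplier (0.8, 0.55, 0.85, 1.0 for lags 1, 3, 7, 9) scales both the
neural gains and the behavioral attention weight, producing the attentional
blink with lag-1 sparing.

**Timing.** 116 ms SOA on a 100 Hz grid: onsets are rounded to the nearest
sample (120, 230, 350, … ms) and those rounded onsets are used everywhere —
synthesis, re-epoching, staircase analyses. Localizer epochs span −50..550 ms
(61 samples, inclusive grid); stream trials span −200..2300 ms so that every
position 1..12 yields a full 0–900 ms per-stimulus epoch (a recording
stopping at 2000 ms would truncate positions 11–12; `epoch_stream` drops
truncated epochs with a warning). Window *selection* everywhere is half-open
[t0, t1): the 400–550 ms analysis window at 100 Hz averages exactly 15
samples.

**Localizer.** Single-stimulus trials contain all four stages at gain 1,
including the sustain: the localizer stimulus is attended and reported, and
this choice reproduces the biphasic profile of early-trained classifiers
(transient peak, chance, late re-rise) seen in within-task generalization.

**Sizes and SNR (the study conditions).** 15 subjects (the emulated study's
N), 200 localizer and 120 RSVP trials per subject, 30 sensors, noise_sd 0.8
(per sensor per sample, against stage amplitudes of order 1 spread over a
unit-norm topography — single-trial decoding peaks around 0.6, comfortably
above real MEG but in the regime where the weaker contrasts live or die by
the group statistics). Trial counts and channel count are scaled down from
the emulated recordings (300 + 300 trials, 306 channels) to keep a full
validation run in minutes on one CPU; subject count is not scaled because
the signed-rank group tests are the analysis bottleneck (the smallest
one-sided p at N subjects is 2^−N). These values were calibrated once
during development, recorded here and in the dataclass defaults, and define
the conditions for every validation experiment.

## Decoding

Per time sample: z-score each channel-time feature using training-trial
statistics only (refit per cross-validation fold; test data at time t′ is
normalized with the training statistics *at t′*, which keeps
signal-free testing times exactly at chance); fit a linear SVM (liblinear
primal, squared hinge, C = 1, deterministic) one-vs-rest with per-sample
weights 1/count(class) — each category contributes unit total weight, which
makes duplicating a class's trials an exact no-op; calibrate each decision
value with a Platt sigmoid (penalized-ML Newton fit on the training
decisions, prior-corrected targets) and normalize the four sigmoid outputs
to sum to one. "Classification performance" always means this mean
correct-class probability; hard labels (argmax, ties broken by class order)
exist only for confusion matrices.

Cross-task transfer applies the localizer-trained classifiers to stream
epochs without refitting; the stream epochs are z-scored per channel-time
feature across the transferred trials, label-free — nothing is ever fitted
on them. Temporal generalization within a task runs inside the
cross-validation, so train-time and test-time data always come from
disjoint trials; a regression test requires the shipped output to equal an
explicitly train-only reference loop to 1e-12.

The six anchor training times 120–370 ms are named rows of the full
−50..550 ms training grid; the contrasts use the 170 ms (early) and 370 ms
(late) anchors. Onset/offset of a group-averaged timecourse is the first
and last sample strictly above the curve's own median; an all-flat curve has
no defined onset and raises.

## Statistics

Signed-rank tests drop zero differences and mid-rank ties; the null is
enumerated exactly (convolution over doubled ranks) for n ≤ 15 and
approximated by a tie- and continuity-corrected normal beyond. Tests against
chance are one-sided (greater); between-condition tests two-sided; the tail
is recorded in every result. BH-FDR is applied over families declared
before any p-value is computed (testing times; guess levels; position
offsets; training bands), via statsmodels, and is checked against the
step-up formula in the tests. The ART ANOVA aligns responses per effect by
subtracting all other estimated effects (cell means, including the subject
intercept), ranks the aligned values over the whole dataset, and runs a
closed-form balanced within-subject ANOVA on the ranks (error = effect ×
subject); it is cross-checked against statsmodels AnovaRM and its
interaction size is calibrated empirically (0.049–0.054 at 5000 replicates
under a null with both main effects). Note that ART statistics are
invariant to positive-affine, not to general monotone, transforms: the
alignment is linear in the data.

Activation patterns are Cov(data)·w per class, with the covariance taken in
the z-scored space where the weights live and the result mapped back to
sensor units via the stored per-sensor scale. For a one-vs-rest
discriminant the ground-truth forward pattern is the *contrast*
a_c − mean(a_other); recovery is assessed against it (cosine ≈ 0.996 at
noise_sd 0.1), while a binary discriminant recovers the raw injected
topography (cosine > 0.999).

## What the simulator does and does not show

The generator reproduces the features the analysis logic depends on:
linear superposition of time-locked stage responses, category-specific
topographies with bounded overlap, graded vs all-or-none attentional gains
tied to the behavioral reports, lag-dependent resource limits, and
without-replacement guessing. It omits 1/f, temporally and spatially correlated sensor
noise (noise is white by design, so that the decoder's null is exactly
calibrated), eye/cardiac artifacts, head geometry and source
mixing, inter-subject latency variability, and any masking-induced
nonlinearity between successive stimuli. Passing tests therefore
demonstrate that the *pipeline* recovers what was injected under clean
superposition — not that real recordings satisfy those assumptions.

## Numerical conventions

Seeds: every experiment derives all randomness from one integer via
`numpy.random.SeedSequence` spawning; reruns are bit-identical, and CSV
outputs byte-identical. Zero-variance features scale to 1 instead of
dividing by zero. Degenerate behavior distributions (point mass exhausted
by earlier guesses) fall back to uniform over the remaining positions.
Probability rows that sum to zero (never observed in practice) would return
the uniform vector. The anti-alias filter for downsampling is a zero-phase
Hamming FIR at 0.4 × the target Nyquist by default (the 30 Hz low-pass of
the emulated preprocessing is available as an explicit cutoff); the
simulator's kernels are band-limited by construction, so downsampling is
not part of the default pipeline.

## Validation experiments (tests/test_acceptance.py, scripts/acceptance.py)

* Permutation null: 100 label permutations of one 200-trial localizer;
  grand-mean correct-class probability 0.250 ± 0.01.
* Overlap separability: at probe time 1140 ms, the three most recent
  stimuli are decodable through training bands of increasing latency
  (training grid restricted to ≤ 380 ms, before the sustain support), and
  the early-anchor staircase of per-position decodable windows is offset by
  the rounded SOA.
* Gradual recovery: 10 seeds × 15 subjects; group window means across
  T−4..T+2 correlate with the injected gain profile (mean Spearman ρ ≈
  0.93), T..T−2 significant after FDR, T+1/T+2 not.
* Discrete recovery: late-anchor means above chance only for reported
  stimuli, unreported control within 0.01 of chance, Guess 1 > 2 > 3
  ordering across seeds.
* Model identification: 10 paired gradual/discrete runs (4 subjects, 60
  trials each) labelled by the early-vs-late signature, 20/20 correct.
* Oracles: signed-rank vs full 2^n enumeration (1000 datasets, exact);
  BH-FDR vs the hand formula; ART interaction size at 5000 replicates.
* Pattern recovery and the uniform-guesser closed form
  1 − (11/12)(10/11)(9/10) = 1/4.
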