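# Methods

This note records the models, parameter choices and numerical
conventions behind `gazeread`, and what the synthetic experiments do and
do not establish.

## Problem setting

Subjective understanding — the reader's own sense of how well they
understood a text — is reported on a 1–5 scale (1 "aborted", 2
"understood almost nothing", …, 5 "understood everything"). Aborted
texts are excluded from every computation, so the estimation target,
each participant's mean self-rating `U`, lives in [2, 5]. The estimator
is deliberately **participant-independent** (leave-one-participant-out,
LOPO) and **position-agnostic**: it uses only event counts, durations
and velocities, never where fixations land relative to the text, so no
gaze-to-text registration or drift correction is required.

## Event detection

Fixations are found with dispersion-threshold identification (I-DT),
defined here as a *greedy maximal-window* rule: scanning the valid
samples left to right, the window starting at the current sample is
grown while its dispersion `(max x − min x) + (max y − min y)` stays ≤
the threshold; if the maximal window spans ≥ the minimum duration it is
a fixation and scanning resumes after it, otherwise the start advances
one sample. This formulation is exactly reproducible by brute force,
which the test suite uses as an independent oracle (the shipped
implementation is an O(n) two-pointer with monotonic deques).

Parameters (all in `DetectionParams`):

| parameter | default | rationale |
|---|---|---|
| dispersion | 40 px | ≈1° of visual angle at ~70 cm on a desktop monitor |
| min duration | 100 ms | customary lower bound for reading fixations |
| gap split | 200 ms | a longer hole in the valid-sample stream (blink, tracking loss) splits fixation candidates |

I-DT was preferred over velocity-threshold detection because it needs no
velocity estimate, which is unreliable at consumer-tracker rates
(~90 Hz). A velocity-threshold variant could be added behind the same
interface.

Saccades are constructed between consecutive fixations. The signed
length is the centroid displacement projected on the reading axis
(configurable: left-to-right horizontal by default; right-to-left and
top-to-bottom are available but uncalibrated). Direction is backward iff
the signed length is negative; an exactly zero displacement counts
forward, since a regression requires actual backward motion. Return
sweeps to the next line are *not* separated from regressions — both are
backward. Saccade duration is the inter-fixation gap, floored at one
nominal inter-sample interval so velocity stays defined when fixations
abut.

## Features

Per recording: `f1` fixations/character, `f2` forward
saccades/character, `f3` backward saccades/character, `f4` the standard
deviation of the recording's saccade velocities (px/ms, unnormalized).
Character counts come from the session manifest, never from text
content. `f4` uses the population convention (divide by n) because
per-recording saccade counts are modest; it is configurable
(`velocity_std_ddof`).

Because detection emits exactly one saccade per consecutive fixation
pair, contiguous recordings satisfy `f1 = f2 + f3 + 1/n_chars`
identically — `f2` is not an independent quantity in this pipeline. This
identity is asserted in the tests; externally supplied event lists need
not satisfy it and are accepted as-is.

Feature–rating correlations are Pearson, computed per recording by
default (per-participant averaging first is a caller-side choice);
features with zero variance report a missing correlation.

## Estimation

Per participant, features are averaged over included texts into `X`
(arithmetic mean per feature), alongside `U` (mean rating) and the
answer score `S` (fraction correct). Both estimators run through the
same machinery: an SVR (RBF kernel, C = 1.0, ε = 0.1, `gamma="scale"`)
on inputs z-scored with training-fold statistics only, evaluated LOPO,
with predictions clipped post-hoc to [2, 5]. These hyperparameters are
ordinary defaults, echoed into every report; nothing was tuned per
dataset. A degenerate training fold (identical inputs *and* targets)
short-circuits to the constant target with a logged warning.
Participants whose texts were all aborted are dropped before LOPO with
a logged reason.

The text-count ablation subsamples each participant's included texts to
k without replacement (participants with fewer than k texts keep all of
theirs), re-aggregates `X`, `U` and `S` from the subsample,
LOPO-evaluates, and averages MAEs over 20 seeded repeats.

## The synthetic reading model

The generator gives each virtual reader a latent understanding
`u ∈ [2, 5]` and emulates:

- **layout** — the text on virtual lines (40 px character pitch ≈ a
  30 pt CJK glyph, 15 characters/line, 50 px line spacing, 100 px
  margins);
- **scanpath** — a fixation chain advancing `δ` characters per step
  (δ set so the fixation count hits the target rate), with
  within-line regression jumps of 2–8 characters inserted at the
  backward-rate target and return sweeps arising from line breaks;
- **dwell** — per-fixation duration ~ lognormal (mean 300 ms, sd 70 ms,
  floored at 120 ms so every fixation is detectable); the detector
  trims ~one sample interval, giving detected means ≈ 289 ms;
- **sampling** — rendering at 90 Hz with additive Gaussian position
  noise (sd 3 px); no samples are emitted between fixations, as consumer
  trackers rarely yield usable samples during fast movement.

Rate profiles are piecewise-linear in u through the empirically reported
per-level means: fixations/char 0.74 → 0.46, backward saccades/char
0.08 → 0.14, velocity spread 0.20 → 0.12 px/ms, around a mean saccade
velocity of 0.32 px/ms. Two modelling conventions deserve emphasis:

- **Velocities, not flight times.** Per-saccade velocity is drawn from a
  gamma distribution with the target mean/sd, and the inter-fixation gap
  is derived as `|length|/velocity` minus one sampling interval (to
  offset detection edge-trimming). The reported velocity moments imply
  "durations" of hundreds of ms — far beyond physiological saccade
  flight times — so these gaps reproduce the printed moments, not
  oculomotor physiology. A gamma (rather than lognormal) tail keeps fast
  draws from colliding with the one-sample-interval duration floor,
  which would otherwise inflate the detected spread.
- **Backward rate as the dial.** Because the pipeline identity pins
  `f2 = f1 − f3 − 1/n_chars`, only two of the three count features can
  be set independently; the generator targets `f1` and `f3` and lets
  `f2` be the remainder (~0.66 at u = 2 down to ~0.31 at u = 5). The
  published per-level `f2` values are not reproducible simultaneously
  with `f1` and `f3` under this identity, which suggests the original
  detector did not emit one saccade per fixation pair.

Cohorts: each participant's skill is drawn once from the empirical
rating distribution over levels 2–5 (proportions 45/23/74/137 of 279);
all their texts share that true understanding. The self-report is the
skill jittered by N(0, 0.3), rounded, clamped to 2..5 — self-ratings are
noisy, and this magnitude leaves feature-based recovery possible while
blurring adjacent levels. Answer correctness is Bernoulli with
probability `0.4 + 0.13(u − 2)` (0.40 at u = 2 to 0.79 at u = 5),
making the answer baseline informative but markedly noisier than the
gaze features: inverting a 19-text answer score (sd ≈ 0.10) onto the
understanding scale carries an intrinsic error near ±0.8 levels.
An `abort_rate` option injects rating-1 texts (default 0).

**What passing tests show — and don't.** The calibration loop
(simulate → detect → extract) recovers the per-level feature means
within a few percent, so the pipeline is internally consistent and the
estimator demonstrably learns a signal of the kind reported for human
readers. It does *not* show performance on real recordings: the
simulator has no vertical drift, no word-level landing-site effects, no
smooth "fooling" behaviors (reading on without understanding, or
rereading despite full understanding), and its noise is stationary
Gaussian. Human-cohort error levels are therefore not claimed.

## Numerical conventions and degenerate inputs

- Time in ms, screen coordinates in px (origin top-left, y down).
- Floats serialize with 17 significant digits; table readers use
  round-trip float parsing (the pandas fast path is lossy).
- Recordings with no valid samples detect to an empty event list;
  recordings without saccades yield `f2 = f3 = f4 = 0` with a warning.
- Population standard deviations throughout the descriptive statistics;
  the forward/backward ratio is missing when a recording has no
  backward saccades.
- All simulation is driven by `numpy.random.Generator` seeded
  explicitly; identical seeds give byte-identical recordings.

## Problem sizes

The reference experiments use the study-shaped cohort (17 participants
× 19 texts × ~210 characters) and 500 simulated texts per understanding
level for calibration checks; both run in well under a minute per
evaluation on one CPU.

## Known limitations

- The ablation's monotone-degradation expectation can fail for the
  *answer* baseline on particular cohort draws: when the answer channel
  is near its noise ceiling (a few participants with atypical answer
  scores), its MAE is flat in the text count rather than decreasing,
  and a coarse 2-text answer score can, by luck, edge out the full
  evaluation. The gaze estimator has not shown this behavior.
- Regression depths, line geometry and the u-independence of fixation
  durations are modelling conveniences, not fitted quantities; only the
  per-level feature means and the event-moment plausibility bands are
  calibrated.
- Right-to-left and vertical reading axes are implemented but
  uncalibrated; the simulator is horizontal-only.
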