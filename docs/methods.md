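# Methods

This note documents the models and procedures implemented in `qrentrain`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish about real data.

## Units and time alignment

Annotation times are integer milliseconds; video runs at 25 fps by
default, so one frame equals the 40 ms resolution of the annotations. A
time `t` maps to frame `floor(t · fps / 1000)`; segment windows are
half-open `[onset, offset)`. The floor convention is a package choice —
any consistent rounding rule would do, and the synthetic generator emits
frame-aligned times so the mapping is exact.

## Kinematics

Displacement series are 1-D movement magnitudes (Euclidean distance
between consecutive frame positions), which makes the signal invariant to
where a speaker sits and how the camera is rotated, and lets DTW compare
differently positioned speakers. Frames with keypoint confidence below
0.3 are linearly interpolated from the nearest valid neighbours (edges
held); segments with more than 50% invalid frames are rejected and logged.
Both thresholds are conventional pose-tracking practice and configurable.
No smoothing is applied by default; a centred moving average is available
(`smoothing_window`). An optional per-speaker scale normalization exists
but is off by default: the chance-level and association tests are
contrasts, so a global pixel scale cancels.

## DTW

Local cost `|x_i − y_j|`; step patterns `symmetric1` (all moves weight 1,
normalization N) and `symmetric2` (diagonal weight 2, normalization
N + M). `symmetric2` is the default because it is the default of the
standard DTW packages and its normalization is symmetric in the two
series. No warping window by default; a Sakoe–Chiba band is available.
The dynamic program is verified, exhaustively for short series, against
`brute_force_dtw`, an independent path-enumeration oracle with the same
cost convention (first cell weight 1, each subsequent move weighted by the
step pattern). One useful caution for interpretation: for a response that
is the question shifted by a constant `c`, the normalized distance is at
most `c` but generally *below* it, because warping exploits within-series
level changes; equality holds only when warping cannot help (e.g. a
constant series).

## Pitch

A short-time normalized-autocorrelation tracker: frames of `3/floor`
seconds (40 ms at the 75 Hz floor) advancing by 10 ms; per frame the
normalized autocorrelation is computed by FFT and rescaled by the
overlapping-window energies, the best lag inside [sr/ceiling, sr/floor]
is taken (smallest lag among near-ties, parabolic refinement), and the
frame is voiced if the peak exceeds 0.45. A sub-lag harmonic check
rejects frames whose true fundamental lies above the ceiling: if the
autocorrelation at lag/k (k = 2, 3, 4) reaches 90% of the peak, the real
period is the shorter one, and a fundamental above 300 Hz must not
masquerade as its subharmonic. On synthetic harmonic complexes the
tracker is accurate to well under 1 Hz across 80–290 Hz.

The segment statistic is the **mean** F0 over voiced frames. The maximum
is implemented behind `statistic: max` because both summaries are common
in prosodic-matching work and sources differ on which to prefer; the mean
is the default and the two must not be mixed within one analysis.
Segments with no voiced frame make the pair's mismatch undefined; such
pairs are dropped from prosodic models only, never from kinematic ones.

## EQ scoring

40 target items worth 0–2 points each (total 0–80); fillers never count.
Skipped items are imputed with the mean score of all loaded respondents on
that item, rounded to the closest integer with half-up ties (the tie rule
is a package choice; "closest integer" alone does not fix it). The dyad
predictor is the absolute difference of the two imputed totals.

## Mixed models and tests

All model comparisons are likelihood-ratio tests between nested linear
mixed models fit by **maximum likelihood** (REML likelihoods are not
comparable when fixed effects differ). The random structure is a single
intercept for the combined `dyad:responder` identifier — the responder
realizes the entrainment, and a single combined factor is the stable
alternative to nested dyad/participant effects, which are prone to
singular fits at this design size. Condition is coded real = 0,
pseudo = 1, so a positive beta means pseudo-pairs are more dissimilar.
`chi2 = max(0, 2·(ll_full − ll_null))` with df = 1 and an upper-tail
chi-square p. Holm's step-down correction is applied to the family
{head, hand}; the prosodic test is a singleton family. Fits use
statsmodels' MixedLM; boundary fits (zero random-effect variance) are
flagged on the result rather than dropped, and the implementation is
cross-checked against lme4's ML fits in the test suite.

Pseudo-pairs are built per dyad by rejection-sampling uniform
permutations until a derangement appears (expected ≈ e tries, exact
uniformity over derangements). Dyads contributing a single pair admit no
derangement and are excluded from the surrogate set with a log message.

Partial correlations use the textbook closed form
`r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))` on complete cases,
with degenerate controls (|r| → 1) raising instead of returning NaN.

## The synthetic generator

Each speaker's articulators move as independent smooth non-negative
processes: unit-variance Gaussian noise low-pass filtered with a Gaussian
kernel (5-frame scale), scaled to a 20 ± 4 px/frame baseline and
rectified. Durations are uniform on 500–4,000 ms by default (inside the
observed real-conversation range of roughly 0.1–13 s; the defaults trade
tail realism for replicate throughput). Response motion is a
time-rescaled copy of the source plus smooth noise.

Coupling is expressed directly in the dependent variable: the generator
measures the mean normalized DTW distance over a grid of noise amplitudes
(Monte-Carlo probes with common random numbers, so the *shape* of the
amplitude–distance curve is precise) and inverts the curve per pair so
that the expected distance equals
`coupling_intercept + coupling_slope_per_eq_point · |ΔEQ| + responder offset`
(offsets N(0, 0.3) give the random-intercept structure the models
assume). This is what makes "the planted slope" directly comparable to
the fitted fixed effect. With `adjacency_specific=False` the copied
source is not the paired question — by default a fresh independent
process (`independent`), with `dyad_latent` and `other_question` variants
available — which destroys pair-specific coupling while keeping
within-dyad exchangeability exact.

EQ totals are drawn N(44, 10) truncated to [0, 80] and decomposed into
random 40-item sheets that sum exactly to the total; items are skipped
with probability 0.02. The ground truth records the *post-imputation*
totals, which are what the pipeline can recover; with no missing items
the recovery is exact. Audio is a per-segment harmonic complex (4
partials): questioners speak near their base F0 (uniform 90–220 Hz), and
responders echo the question's F0 plus N(0, 5 Hz) jitter, so prosodic
matching is high within pairs but carries no EQ signal.

What the generator does **not** emulate: natural speech spectra and
voicing variation, gesture morphology, within-turn pauses, occlusion
structure of real pose tracking, or the corpus's empirical EQ
distribution. Passing tests therefore establish that the pipeline's
statistics behave as designed under a controlled data-generating process,
not that real conversations satisfy the model.

## Operating characteristics and a known limitation

At the reference scale (20 dyads × 30 pairs, 1,200 records), measured by
simulation in the acceptance suite:

* the surrogate test detects adjacency-specific coupling essentially
  always, with pseudo-pairs more distant than real pairs;
* the EQ-association model recovers the planted slope without bias, with
  ±2 SE coverage near the ~92% expected when normal quantiles are used
  with only 20 dyads of between-dyad information, and rejects at ≈ α
  under a zero slope;
* the surrogate test's type-I error under the exchangeable null is far
  **below** nominal (≲1% at α = 5%). This is structural, not a bug: the
  within-dyad derangement reuses every question and response segment
  exactly once per condition, so segment main effects cancel
  deterministically in the real-vs-pseudo contrast, while the mixed
  model's residual variance still includes them. Any test that treats the
  records as exchangeable observations (including a question-paired
  t-test) inherits this conservatism; the interaction share of DTW
  distance variance caps near 60% across realistic regimes, bounding the
  effective rejection rate well under α. Practically this means
  chance-level *discoveries* made with this design are robust, while its
  null calibration is conservative; an exactly calibrated alternative
  would need a permutation reference over re-derangements.

## Problem sizes

Unit and property tests run on miniature studies (3–6 dyads, ≤ 12 pairs);
replicate-level checks use 100–500 studies of 20 dyads × 30 pairs with
the head articulator only and no audio, which keeps a full suite run in
the minutes range while preserving the reference design size.
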