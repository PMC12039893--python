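# qrentrain

Interpersonal entrainment analysis for conversational question–response
pairs: do interlocutors move and sound more alike across adjacent turns
than chance would predict, and does that coupling track how *different*
the two partners' empathy-quotient (EQ) scores are?

The package is aimed at researchers working with dyadic conversation
corpora annotated for question–response adjacency pairs, with pose-tracked
video (2D keypoints for the nose and both wrists) and per-speaker audio.
Because such corpora typically cannot be redistributed, a first-class
synthetic-study generator with known ground-truth coupling stands in for
the raw data, and every statistical property of the pipeline is validated
against it.

## The measures and the models

**Kinematic entrainment.** For each articulator the per-frame displacement
magnitude `d_t = ‖p_{t+1} − p_t‖` (pixels/frame) is extracted within the
question window (questioner) and the response window (responder). The two
series are compared with dynamic time warping using absolute-difference
local cost and the symmetric2 step pattern; the accumulated path cost is
normalized by `N + M` so series of different durations are comparable.
Head distance uses the nose; hand distance is the mean of the left- and
right-wrist distances. Low distance = high entrainment.

**Prosodic matching.** Mean F0 in the 75–300 Hz band (normalized-
autocorrelation pitch tracker with a sub-lag harmonic check) per segment;
the pair's mismatch is `|F0_Q − F0_R|` in Hz.

**Chance baseline.** Within each dyad, question–response correspondences
are shuffled by a uniformly sampled derangement (no question keeps its own
response; no pairing crosses dyads). For each measure, a likelihood-ratio
test compares `distance ~ 1 + (1 | dyad:responder)` against
`… + condition` (real vs pseudo), both fit by maximum likelihood. Holm's
step-down correction spans the two kinematic tests.

**EQ association.** EQ sheets (60 items, 40 scored, total 0–80) receive
group-mean imputation of skipped items (rounded half-up); the dyad
predictor is `|ΔEQ|`, the absolute difference between partners' totals.
The same nested-model LRT asks whether `|ΔEQ|` explains entrainment, and a
post hoc network computes pairwise partial correlations between the three
measures, each controlling the third.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a generated
study (8 dyads × 12 pairs, seed 42, planted coupling
`E[distance] = 1.0 + 0.05·|ΔEQ|` px/step):

```
python analysis/01_simulate_study.py   # export study to scratch/
python analysis/02_score_pairs.py      # records -> results/records.csv
python analysis/03_chance_level_tests.py
python analysis/04_eq_associations.py
python analysis/05_entrainment_network.py
```

Output of the scoring and testing steps:

```
  pseudo: head 2.753, hand 2.656 (px/step), F0 mismatch 29.8 Hz
  real:   head 1.535, hand 1.407 (px/step), F0 mismatch  3.7 Hz

  head_distance: chi2(1) = 36.439, Holm p = 1.57e-09, beta = +1.218
  hand_distance: chi2(1) = 82.508, Holm p = 2.11e-19, beta = +1.249
  f0_diff:       chi2(1) = 62.197, Holm p = 3.11e-15, beta = +26.099

  head_distance: chi2(1) = 4.861,  Holm p = 2.75e-02, slope = +0.0551 ± 0.0231
  hand_distance: chi2(1) = 12.154, Holm p = 9.80e-04, slope = +0.0612 ± 0.0143
  f0_diff:       chi2(1) = 0.930,  Holm p = 3.35e-01, slope = -0.0438 ± 0.0454
```

Reading: real pairs are far more similar than the dyad's intrinsic
similarity alone produces (positive condition beta = pseudo-pairs more
distant); the fitted kinematic |ΔEQ| slopes cover the planted 0.05
px/step per EQ point within 2 SE; and the F0 mismatch, generated
independently of EQ, shows the expected null.

The same pipeline is scriptable from a shell via the `qrentrain` CLI
(`simulate`, `score`, `surrogate`, `associate`, `network`), each accepting
a YAML config and `--seed`.

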