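# Methods

## The task and the protocol

One trial: fixation cross (1000 ms), then a peripheral circle (8 mm
diameter) and a central digit (1–4) flashed together for 100 ms, then a
random-dot mask (2000 ms). The participant reports the digit and the side(s)
of the circle(s). Fourteen circle positions are defined in cm from screen
center (7 per hemifield, mirror-symmetric, in upper / middle / lower bands
at three eccentricities); viewing distance is 60 cm, and
`cm_to_visual_angle` converts offsets with a plain arctangent.

The main series presents each of 25 configurations exactly 3 times in a
seeded uniform random order: 14 unilateral, 7 bilateral pairs symmetric
about the vertical axis (i with i+7), and 4 diagonal bilateral pairs
(1+10, 3+8, 4+13, 6+11). Counting over the 75 trials gives the constants
the coefficients need — 33 bilateral trials (BP), 54 lateralized
presentations per side (LP) — and per-position presentation maxima of 6
(positions 2, 5, 7, 9, 12, 14) or 9 (all others). The scorer re-derives BP
and LP from the session's own schedule so truncated protocols remain
scoreable; the canonical values are asserted only for the standard series.

Choices where the protocol leaves freedom:

* **Digit assignment** — i.i.d. uniform over {1, 2, 3, 4} from the schedule
  RNG (maximally uninformative, reproducible).
* **Randomization** — an unconstrained uniform permutation of the 75
  trials; no anti-repetition constraint is imposed.
* **Training series** — 7 trials on a fixed linear duration ladder
  1000, 850, 700, 550, 400, 250, 100 ms, sampling left/right, near/far,
  upper/lower and bilateral displays.

## Scoring rules

Scoring is per-side, per-trial, independent: *miss* = presented ∧ ¬reported
(into LSU/RSU or LSB/RSB by trial kind, plus the position's counter);
*hallucination* = reported ∧ ¬presented (RH/LH; opportunities exist only on
the 21 unilateral trials of the opposite side); *digit error* = wrong or
indefinite digit (NIR/NIL by presented side on unilateral trials, NIB on
bilateral ones, independent of whether the circle was caught). An
indefinite report ("something flashed") carries an empty side set — scored
as omissions on every presented side and no hallucination — and an
INDEFINITE digit, scored as a digit error. A "both" report on a
unilateral-left trial scores a detection plus one RH. These are the only
readings consistent with the variable definitions ("responses indicating
right when there was no circle on the right side").

Coefficients follow the formulas in the README. Two numerical conventions:

* A zero denominator (e.g. every presentation missed) yields a tagged
  missing value (`None`) with an `UndefinedCoefficientWarning` — never a
  silent clamp, because total-miss sessions are clinically meaningful.
* KEf_all is often described as a 0–1 quantity, but its formula is negative
  whenever hallucinations outnumber detections; the implementation follows
  the formula and the true range (−1, 1].

## Diagnostic classification

Two published single-feature rules are built in: LSB ≥ 14 ⇒ neglect, and
KA_all ≥ 0.17 ⇒ neglect (boundary values classify as neglect; an undefined
KA_all raises a classification error rather than guessing).

The CART inducer is written from scratch because the splitting rule is part
of the method: greedy binary recursive partitioning minimizing weighted
child Gini impurity, candidate thresholds at midpoints of consecutive
sorted unique feature values. Hyperparameters use the rpart vocabulary so
fits can be compared with an independent implementation: a node is split
only if it holds ≥ `minsplit` (20) samples, both children hold
≥ `minbucket` (7), and the split lowers the resubstitution
misclassification count by at least `cp` (0.01) × the root's
misclassification count. Impurity ties break by (feature name, threshold)
ascending; leaf majority ties resolve to *no-neglect*, deliberately
favoring specificity. Cross-validation is stratified by class (the protocol
description says only "equal-sized folds") and fully seeded; both pooled-CV
and resubstitution metrics are reported, clearly labelled, since published
tree metrics are often ambiguous between the two. Zero-denominator metrics
(e.g. precision with no positive predictions) are reported as `None`.

The test suite checks the inducer against exhaustive enumeration with exact
rational arithmetic on small instances and against scikit-learn's CART on
an unambiguous split; scikit-learn is never used in the implementation.

## Spatial analyses

*Vertical neglect*: omissions above the midline (positions 1, 4, 8, 11)
vs below it (3, 6, 10, 13), compared with a Wilcoxon signed-rank test under
the directional hypothesis down > up (lower-field deficits are the common
clinical pattern). A `side_filter` restricts the sets to one hemifield;
the default uses all four positions per set.

*Nonparametric tests*: the signed-rank and Mann-Whitney statistics are
computed on tie-corrected (average) ranks. P-values are exact by full
enumeration — all 2^n sign assignments when ≤ 12 non-zero pairs remain; all
C(n1+n2, n1) group assignments while n1·n2 ≤ 400 — and otherwise use a
normal approximation with tie-corrected variance and a 0.5 continuity
correction. Effect sizes are rank-biserial: (W⁺ − W⁻)/(W⁺ + W⁻) for paired
data, 1 − 2U/(n1·n2) for independent groups. Holm's step-down correction
delegates to statsmodels.

*Per-position screening*: each position's omission count is binarized at
the pooled-cohort median — the lower median (a sample value) for even
sizes, ties at the median coding as impaired — and sensitivity/specificity
are computed against the group label. When an entire cohort sits at or
above the median (e.g. a position nobody misses), every subject codes
impaired and the position degenerates to sensitivity 1 / specificity 0;
this is flagged with a warning rather than hidden, as it is exactly the
mechanism that produces such cells in real cohorts.

*Phi coefficient* (Guilford): (ad − bc)/√((a+b)(c+d)(a+c)(b+d)) for 2×2
agreement tables; zero margins yield a tagged `None`.

## The generative model

A subject is a vector of Bernoulli parameters. Each presented circle is
detected independently with probability

    p = p_base(side) × vertical_penalty^[y<0] × extinction_penalty^[bilateral ∧ left]

— multiplicative factors chosen for analytic tractability: every expected
count is then a sum of Bernoulli means over the schedule, which
`expected_scoresheet` computes exactly, and plug-in coefficients follow by
evaluating the scoring formulas at those means (a plug-in approximation,
not the expectation of a ratio). Hallucinations are drawn independently of
detection on the opposite side's unilateral trials; digit correctness
depends only on trial kind (unilateral vs bilateral). Failed digit reports
are 50/50 a uniformly wrong digit or an indefinite answer. No eccentricity
term, no fatigue/learning across trials, and no miss-triggered allochiria
coupling are modelled; these are the main respects in which the simulator
is simpler than patient behavior, so passing tests demonstrate the
correctness of the pipeline, not the realism of any particular patient.

### Cohort presets and calibration

Two presets emulate a validation cohort of 38 neglect and 64 no-neglect
subjects. Detection parameters are inverted in closed form from group-mean
productivity anchors (neglect group: KPrL_bilateral 0.097, KPrL_all 0.145,
KPrR_all 0.800; no-neglect group: 0.759, 0.767, 0.881) using the standard
schedule's opportunity counts — per hemifield 21 unilateral presentations
(6 lower-band) and 33 bilateral (12 lower-band):

    KPrL_bilateral = p·e·(21 + 12v)/33
    KPrL_all       = p·((15 + 6v) + e·(21 + 12v))/54
    KPrR_all       = p_r·(36 + 18v)/54

with v fixed per group (0.85 neglect-like, 0.90 control-like, a mild
lower-field bias). This gives p_left ≈ 0.23, extinction ≈ 0.45,
p_right ≈ 0.84 for the neglect preset and p_left ≈ 0.80,
extinction ≈ 0.98, p_right ≈ 0.91 for controls. Hallucination and
digit-error rates are group means divided by opportunity counts (e.g.
h_right = 1.632/21 for the neglect preset). Subject heterogeneity is a
truncated normal spread per parameter, tuned only to give realistic
overlap, not to match any published dispersion. Because the mean of a ratio
over heterogeneous subjects is not the ratio of mean counts, the cohort's
mean KA_all (~0.69 neglect / ~0.08 control) sits somewhat below the
corresponding published group means (0.746 / 0.104); the KPr anchors were
kept rather than re-tuning toward KA.

On this calibrated cohort both published rules reach sensitivity 1.0 with
specificity ~0.83–0.92 (seed-dependent), the position screen ranks left
positions far above right ones (mean Youden ~0.65 vs ~0.07), and the
far-right positions that nobody misses degenerate to sensitivity 1 /
specificity 0 — the same qualitative structure reported for the clinical
cohort. Exact reproduction of the clinical tables would require the
original patient data and is not claimed.

## Problem sizes

The test suite simulates one 102-subject cohort (session-scoped fixture),
500 sessions for parameter recovery, and 300-session Monte-Carlo checks per
profile; the acceptance script uses the same sizes. These sizes give
standard errors small enough for 4-SE recovery bounds while keeping a full
run in seconds.

## Known limitations

* The simulator's independence assumptions (across circles, trials and
  tasks) ignore attentional-blink-like sequential effects and any coupling
  between digit load and spatial misses within a trial.
* The exact-enumeration p-values scale exponentially; the enumeration
  limits (12 pairs / n1·n2 ≤ 400) are hard-coded and the normal
  approximation takes over beyond them.
* The CART inducer supports numeric features and binary labels only; no
  surrogate splits — a missing feature at prediction time is an error.
* Published visual-angle ranges for the extreme positions do not match a
  plain arctangent at 60 cm; the conversion here documents its own
  convention and makes no claim about the original display geometry.
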