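# Methods

## Problem and scope

`gazerel` studies whether eye-gaze dwell time can replace explicit manual
annotation as the supervision signal for models that predict which parts of
an ICU patient's electronic record a physician will want to see. The unit of
prediction is a *data item* — one displayable series such as all serum
glucose measurements. For each item a binary *target variable* records
whether a reviewing physician sought it as relevant for prerounding (the
constant clinical task); a per-item classifier then predicts that target
from summaries of the patient's structured record. The package implements
the complete comparison — label acquisition from two channels, feature
engineering, per-target model selection, paired evaluation — over a
synthetic data generator with known ground truth, because the original
deidentified ICU records are not publicly available.

## The synthetic generator

The generator is first-class, tested code: every downstream stage is
validated against quantities it knows exactly.

**Cases.** A case spans admission (t = 0 h) to a prediction time (48 h).
Nine variable categories are simulated: vital signs, ventilator settings,
laboratory tests, medication administrations, procedures, microbiology
cultures, intake/output (all time-stamped series), plus six atemporal
demographics and one admission diagnosis (acute kidney failure or acute
respiratory failure, balanced). Each time-series variable is present in a
case with probability `1 − missing_rate` (default 0.85); an absent variable
has no entry at all. Series lengths are Poisson with category-typical means
(24 vitals points per 48 h window down to 2 for procedures). Two latent
properties of every series are drawn with fixed frequencies so the ground
truth below is controlled: the last measurement falls within 24 h of the
prediction time with probability 0.5, and the latest value lies outside the
shared reference range (90–110) with probability 0.3.

**Latent relevance.** Ground truth is a per-item logistic model over three
named case summaries: *recent measurement* (last timestamp within 24 h),
*abnormal latest value*, and *diagnosis*. Default coefficients are
intercept −2.4 (plus N(0, 0.2) per-item jitter), +2.4 for recency, +2.8 for
abnormality, and ±1.5 for diagnosis with the sign alternating across items.
These values were solved for numerically, once, so that the generative
Bayes AUROC — the discrimination of the true probability itself against
labels drawn from it — is ≈ 0.85 under the covariate frequencies above
(computed value 0.856, mean relevance ≈ 0.55). The three-covariate design
is deliberately small enough to verify by hand yet rich enough for
parameter-recovery experiments.

**Sessions.** A review session couples a gaze stream with a layout stream.
The layout shows all present items in four panels of stacked 400×60 px
elements; scrolling is simulated as a fresh layout snapshot every 2 s that
shifts every rectangle 40 px upward, so dwell accumulation must join the
two streams on timestamps. For each present item a relevance draw
~ Bernoulli(p_item) selects a lognormal intended-dwell mode: log-mean
1200 ms when relevant, 60 ms when irrelevant, σ = 0.5 on the log scale —
the two modes sit clearly on either side of the 250 ms labeling threshold.
Gaze is emitted at 60 Hz as fixation bouts: consecutive samples at the
element's current centre for the intended duration, separated by three
transition samples attributed to no element. No saccade physics is
modeled; the bouts exist to exercise the attribution code path, and the
emitted stream reproduces each intended dwell to within one sample period
when re-processed. Manual selections equal the relevance draws with
independent flips at `manual_flip_noise` (default 0.05). Sessions can be
degraded for QC testing: with configured probabilities, most gaze samples
are marked invalid (head outside the tracking box) or the selection record
is omitted entirely.

**What the generator does not emulate.** Free-text notes, pharmacology,
realistic inter-variable correlation, reviewer heterogeneity, saccade
velocity profiles, and calibration drift of a physical eye tracker. Passing
tests therefore demonstrate the correctness and statistical behavior of the
pipeline under a known generative process, not clinical performance on real
ICU records.

## Gaze processing

Coordinates are screen pixels, origin top-left, y downward; rectangles are
half-open (`x0 ≤ x < x1`, `y0 ≤ y < y1`), which makes boundary behavior
exact and testable. Each valid sample is attributed to the element
containing it under the latest layout snapshot at or before its timestamp
(first element wins on overlap, warned once per session) and contributes
`min(next_timestamp − timestamp, max_gap_ms)` to that item's dwell; the
last sample contributes the nominal sample period (median inter-sample
gap). The `max_gap_ms` cap (default 100 ms) prevents capture dropouts from
inflating dwell. Raw per-sample interval attribution is used instead of
fixation/saccade event detection: region-level dwell is the quantity of
interest and the low-cost tracker class being emulated does not support
reliable event parsing. Dwell accumulates across revisits (total dwell, not
longest visit).

Gaze labels are positive when total dwell ≥ 250 ms — inclusive, so a dwell
of exactly 250 ms is positive. Manual labels are positive when the item's
checkbox was selected. Items without data in a case are *absent* and the
case is excluded from that item's training and evaluation rows. Session QC
discards sessions whose valid-sample fraction is below
`min_valid_fraction` (default 0.5; "incompleteness" is not quantified
further anywhere authoritative, so the cutoff is configurable) or whose
selection record is missing.

## Featurization

Every time-series variable maps to a fixed, named feature group: 35
features per laboratory test and vital sign, 31 per ventilator setting, 9
per medication, 4 per culture and per procedure, 2 per intake/output
variable, and 1 integer-coded feature per atemporal variable. The named
members of the numeric 35 (first/last/highest/lowest value, last-two
difference, ever-measured) are fixed by the study design; the remaining
members are frozen in `features.NUMERIC_FEATURES`, drawn from the families
count, recency, extreme times, central tendency, dispersion, range, slopes
(whole stay and last 24 h), last-24 h aggregates, consecutive-difference
statistics, mean-crossing counts, and measurement-spacing summaries. The
ventilator group drops the four slope/step features that presume a
continuous scale. The last-two difference is `last − second_to_last`.
Features undefined for short series (e.g. a standard deviation of one
point) are emitted as missing, as is the entire group of a variable absent
from a case; the missing marker in CSV output is the empty field.

Preprocessing runs in a fixed order on the training matrix: (1) drop
columns with at most one distinct observed value, (2) keep one
representative per class of columns identical on every case (NaNs compare
equal; the canonically first column survives), (3) impute two ways —
median/mode (mode ties break to the smallest value) and model-based
(linear regression for continuous, logistic for nominal columns, each
incomplete column regressed on all others median-prefilled, with a logged
median/mode fallback for degenerate fits). Both variants leave observed
cells bit-identical and share the schema. Evaluation rows are restricted
to the training-retained columns and filled with training medians/modes in
both variants: imputation is a training-set operation and no statistic may
leak from evaluation data.

## Modeling

A target is eligible when it has strictly more than 3 positive training
labels among non-absent cases. Screening evaluates each predictor
variable's group alone — a 25-tree random forest under stratified 5-fold
CV, pooled out-of-fold AUROC — and keeps the group iff AUROC > 0.55
strictly; screening runs per (target × imputation variant), and the
screening learner is configurable because nothing fixes it to the final
classifier. Candidate selection compares {median, regression} ×
{L2 logistic regression (C = 1, standardized), RBF SVC (C = 1,
standardized, decision values rank-mapped to [0, 1]), random forest
(50 trees)} by mean fold AUROC with one shared stratified fold assignment
(k reduced to min(5, n_pos, n_neg) when a class is tiny, logged); ties
break median-before-regression, logistic/SVC/forest. The winner refits on
all training rows. When no group survives screening the target gets an
intercept-only fallback scoring the training prevalence, so the paired
evaluation always has a model per target. Hyperparameters are fixed
package defaults with no inner tuning loop; forest sizes (50 final, 25
screening) are sized for single-CPU desk-scale runs.

## Paired evaluation

Manual selection is always the evaluation gold standard — gaze labels are
never evaluation truth, which is acknowledged to favor manually trained
models. AUROC is the Mann-Whitney rank statistic with ties counted half.
Per pair, percentile bootstrap CIs (B = 2000, α = 0.05) resample
evaluation cases, the same resample scoring both models; single-class
resamples are redrawn and counted; a pair is significant when the CI of
the per-resample paired AUROC difference excludes zero (uncorrected, as is
conventional for this descriptive per-pair flag). The cross-target paired
Wilcoxon signed-rank test drops zero differences, midranks ties, uses an
exact enumerated null for ≤ 12 nonzero pairs (enumeration is exact even
with ties), and a tie-corrected normal approximation with continuity
correction beyond that; all-zero differences report p = 1 with a
degeneracy flag. "Average difference in AUROC values" is interpreted as
the per-resample paired-difference distribution rather than the difference
of bootstrap means.

## Pipeline and reproducibility

Stages (`simulate → label → featurize → train ×2 → evaluate`) write plain
text outputs plus JSON manifests (config hash, seed, input checksums, row
counts). A single global seed spawns per-stage and per-session substreams
through `numpy.random.SeedSequence`, so a rerun with an unchanged config
reproduces byte-identical text outputs. The evaluation unit is one
(case × reviewer) session, mirroring a design where 18 evaluation cases
are each reviewed by 4 physicians.

## Problem sizes used by the test suite and acceptance script

The default study run (analysis scripts and `scripts/acceptance.py`) uses
178 training sessions, 18 × 4 evaluation sessions, and a 16-variable
inventory — a deliberately scaled-down version of a full ICU inventory
(hundreds of labs and medications) chosen so a complete run takes a few
minutes on one CPU. The parameter-recovery experiment uses n = 500
training cases, 75 × 4 evaluation sessions, and a 10-variable inventory
restricted to categories (vitals, labs, ventilator, medications) whose
feature groups contain recency-of-last-measurement and latest-value
features: those are exactly the summaries the latent model scores, so its
Bayes AUROC is attainable by construction. Intake/output (2 features) and
culture/procedure (4 features) groups cannot express the abnormal-latest
covariate, which bounds their achievable AUROC below the generative
optimum regardless of sample size — a structural property worth knowing
when interpreting per-category results. The Wilcoxon type-I-error and
bootstrap-coverage checks simulate at the score level (100 and 200
replicates respectively); the coverage acceptance band is 95% ± 3 binomial
standard errors widened slightly for the known mild anticonservatism of
percentile intervals at n = 100.

## Known limitations

- Synthetic series are mutually independent given the latent covariates;
  real panels are strongly correlated, so duplicate-feature merging is
  rarer here than on real data.
- The lognormal dwell model is a modeling choice; no authoritative
  distributional description of real per-item dwell exists.
- The shared reference range (90–110) for all numeric series trades realism
  for a hand-checkable abnormality flag.
- The intercept-only fallback makes degenerate targets evaluable but their
  AUROC is 0.5 by construction; such targets dilute both arms equally.
- With a 16-variable inventory, per-target evaluation rests on at most ~56
  evaluation sessions; CIs are correspondingly wide.
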