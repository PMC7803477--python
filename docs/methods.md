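# Methods

## Minute-level step processing

The device substrate is a per-participant sequence of minute step counts
covering whole calendar days (minute 0 = local midnight; missing minutes
are explicit).  Processing applies, in order:

1. **Artifact recoding.** Minutes with more than 200 steps are recoded
   missing.  200 itself is kept (the rule is "more than").  The transform
   is pure and idempotent.
2. **Nonwear detection.** Maximal runs of ≥120 contiguous *exactly-zero*
   minutes are nonwear; missing minutes break runs.  Runs may span
   midnight; intervals are 0-based half-open `[start, end)` and
   apportioned to calendar days during summary.
3. **Classification.** Every minute gets exactly one label: NONWEAR,
   MISSING, or a cadence class over closed integer bins — sedentary 0–9,
   walking 10–100, moderate 101–130, vigorous 131–200 steps/min.
4. **Summaries.** Per day: wear = 1440 − nonwear − missing; a day is
   adequate at ≥600 wear minutes.  Per week (7 consecutive adequate days):
   steps/d and class-minute totals in the questionnaire-matched units.

Two points were genuinely open and are decided as follows, with a config
switch for the alternative:

* **Low-step long bouts.** The sedentary definition ("bouts shorter than
  120 consecutive minutes with 0–9 steps") read literally leaves a
  ≥120-minute run of 0–9-step minutes containing some nonzero minutes
  unlabeled.  Default: the 120-minute exclusion applies only to all-zero
  runs (the nonwear rule); every worn 0–9-step minute is sedentary.
  `StepConfig(long_low_bouts="nonwear")` selects the alternative reading.
* **Missing minutes and wear.** A >200-step artifact implies the device
  was worn but the value is unusable; counting it as wear would inflate
  denominators.  Missing minutes count toward neither wear nor nonwear.

All thresholds (200, 120, 600, bin edges) live in `StepConfig`.

## IPAQ cleaning and scoring

Cleaning follows the public IPAQ scoring protocol: per-category episodes
under 10 min/day are recoded to 0; the >960 min/day total-activity
validity cap is evaluated on the post-floor, *pre-truncation* totals
(after the 180-minute cap the rule could never fire, since 3 × 180 < 960);
then each category is truncated at 180 min/day.  Every applied rule is
recorded in `cleaning_flags` and the original response is retained.  A
category with both items unanswered is treated as no activity (flagged); a
half-answered category invalidates the response.  Scoring: weekly minutes
= days × min/day; overall activity = 3.3/4.0/8.0 MET × weekly hours of
walking/moderate/vigorous; sedentary time = 7 × sitting min/day.  The MET
multipliers and every cleaning rule are configurable
(`MetValues`, `IpaqCleaningConfig`; rules can be disabled with `None`).

## Pairing and attachment rules

The IPAQ asks about "the last 7 days", so a response's recall window is
anchored to the 7 days ending the day before the response date.  An
observation is emitted only when all 7 days are adequate (a ≥k-of-7 mode
with 7/k rescaling exists but is off by default).  The window midpoint
(day 4) is the reference date for all proximity rules.  BMI: weights and
directly reported BMI averaged within ±90 d, heights within ±365 d;
calculated BMI = weight/height²; calculated and reported BMI merged by
median (for two values, their mean).  Covariates: for each block
(demographics, behaviors, clinical) the nearest record within ±365 d with
the block complete; equidistant ties go to the earlier record.  The
comparative analysis set keeps each participant's first observation; the
BMI analysis set keeps every observation with BMI and complete covariates.

## Statistical battery

* **Agreement:** Spearman rank correlation (average ranks, large-sample t
  p-value) and the Wilcoxon matched-pairs signed-rank test.  The signed-
  rank test drops zero differences and midranks ties; for n ≤ 25 the
  two-sided p is exact, from the full null distribution of the positive-
  rank sum computed by subset-sum dynamic programming over doubled ranks
  (equivalent to enumerating all 2ⁿ sign assignments); beyond that, a
  normal approximation with tie correction.
* **Trend:** Cuzick's rank test across ordered categories with equally
  spaced scores and a tie correction.  With two groups it reduces to the
  Wilcoxon rank-sum z (verified in tests); p-values match a 10,000-draw
  permutation reference within Monte-Carlo error.
* **Regressions:** ordinary least squares of untransformed BMI with
  cluster-robust (sandwich) covariance grouped by participant, small-
  sample factor G/(G−1)·(N−1)/(N−K).  "Robust" here means robust standard
  errors, not M-estimation.  Confidence intervals use the normal critical
  value 1.96 (a different critical value, e.g. t with G−1 df, can be
  passed).  Every model adjusts for device wear time, wear location, and
  season; tiers add demographics, then behaviors + clinical conditions,
  cumulatively.  Standardized mode divides each activity predictor by its
  sample SD.  Categorical covariates become first-level-dropped dummies;
  rank deficiency raises an error naming the collinear columns.
* **Battery:** for each of the 6 analogous measure pairs (sedentary,
  walking, moderate, vigorous, total active time, overall activity) and
  each tier: two separate single-predictor models (12 per tier) and one
  combined head-to-head model (6 per tier).
* **Coefficient comparison:** within a combined model, a 1-df Wald test of
  the contrast under the model's cluster covariance.  Across two separate
  models, the equations are re-estimated jointly as a stacked system
  (block-diagonal design, duplicated observations, shared participant
  clustering) and the cross-equation contrast tested under the joint
  sandwich; point estimates are unchanged by the stacking.  The method is
  validated against a cluster bootstrap of the coefficient difference and
  holds its nominal size (empirical type-I error ≈ 5% at α = 0.05 in the
  test suite's 1000-replicate null study).
* **Sensitivity:** the battery and correlations rerun after excluding
  smartphone-sourced rows or torso-worn devices, with excluded counts
  reported.
* No multiple-testing correction is applied by default, matching the
  analysis design this package mirrors.

## Synthetic cohort generator

`GeneratorConfig` defaults define the study conditions; they are
calibrated once to the published activity distributions of the target
population and are not tuned per run:

* **Weekly truth.** Between-participant lognormals: walking median
  1212 min/wk (log-SD 0.30), moderate median 75 min/wk (log-SD 1.0),
  vigorous zero-inflated (45% any; conditional median 14 min/wk, log-SD
  1.4 — overall median 0, 75th percentile ≈ 11 min/wk), a shared
  participant-level activity factor (log-SD 0.18), window-level jitter
  (log-SD 0.10).  Tails are capped at 40/20/6.7 h per week so the linear
  BMI model stays in a plausible range (the caps bind for <1% of draws).
* **Minute assembly.** Each day gets a ≥120-min sleep/nonwear block
  (wear ≈ 16 h/d), occasionally a second one, activity bouts
  (exponential lengths, means 15/10/8 min) carved from sedentary time,
  cadences drawn from in-bin clipped normals (walking 28±18, moderate
  115±8, vigorous 150±12 steps/min), and a sedentary background that is
  zero-step with probability 0.55, else 1–9 steps.  Guard passes force
  bout flanks nonzero and break sedentary zero-runs below 120 minutes, so
  the generated nonwear bouts are *exactly* the detectable ones and
  processing recovers the truth ledger exactly when artifacts are off.
  Artifact minutes (>200 steps) are injected on worn minutes at rate
  5×10⁻⁴.
* **Recall model.** Reported weekly minutes = (truth × multiplicative
  bias + additive bias) × mean-one lognormal noise, then discretized to
  days/week × integer min/day.  Default biases reproduce the observed
  discrepancy directions: walking 0.17 and sitting 0.48 (under-report),
  moderate 1.2 and vigorous 1.5 plus 70 min/wk (over-report).
* **Outcome.** BMI = 24 + 0.08·h_sed − 0.18·h_walk − 0.41·h_mod −
  0.84·h_vig (kg/m² per true weekly hour; the published fully adjusted
  device coefficients) + covariate effects + participant effect (SD 3.0)
  + window noise (SD 3.3).  The model is strictly linear — no floor or
  ceiling — because the parameter-recovery studies assume a correctly
  specified outcome.  Covariates are drawn from Table-1-style marginals
  and are independent of activity.
* **Structure.** 71.5% wrist-worn, 5.5% smartphone-sourced, 19% of
  participants contribute a second window (giving the clustered,
  repeated-observation structure the sandwich errors exist for).

Calibration achieved by these defaults (checked by simulation, not
asserted as equalities): median ≈ 8,800 steps/d and between-participant
SD ≈ 3,300 steps/d, inside the ±15% / ±20% bands around the published
8,622 and 3,663; weekly walking/moderate/vigorous/sedentary IQRs close to
the published ones.  One published pair cannot be reproduced jointly:
wear 17.1 h/d together with sedentary 87.2 h/wk is arithmetically
inconsistent with wear = sedentary + active time under this package's
wear accounting, so the generator uses wear ≈ 16 h/d and matches the
sedentary distribution instead — only the steps/d median and SD are
treated as hard calibration targets.

Two generation paths share the same truth and measurement model.  The
minute-level path (`generate_cohort`) emits everything the pipeline
reads and is used for round-trip and calibration checks.  The weekly
path (`generate_weekly_cohort`) draws the weekly truth directly into an
analysis table — device measures equal truth times mean-one lognormal
noise (SD 0 by default, mirroring the minute path's exactness) — and is
used for the 200-replicate estimator studies, where re-synthesising ~6
million minutes per replicate would add nothing about the estimators.

### What the generator does not emulate

Within-week day-to-day autocorrelation of activity (days are split
near-evenly), device-model heterogeneity, heart-rate or sleep channels,
seasonal activity differences, and activities a wrist tracker cannot see
(cycling, swimming).  Passing tests therefore demonstrate the pipeline's
correctness and the estimators' calibration under the stated data model,
not agreement with any particular real cohort.

## Numerical and degenerate-input choices

Exact-zero comparison defines zero runs (missing breaks a run); cadence
bins are closed integer ranges, so boundary minutes are never ambiguous.
Constant inputs to Spearman, all-zero difference sets for the signed-rank
test, single-group trend tests, empty analysis sets, and exclusions that
empty a dataset all raise explicit errors rather than returning NaN.  The
signed-rank exact distribution doubles midranks to integers, so .5 ranks
are handled without floating-point accumulation.  Stacked-system point
estimates equal the separate fits by block-diagonality; the self-
comparison of a model with itself returns a zero difference up to solver
round-off.

## Simulation sizes

The test suite uses 1000 random series for the processing oracles, 200
replicates of n = 586 cohorts for recovery/coverage and attenuation, 1000
replicates for the comparison test's size, and a 3000-participant draw
for distribution calibration; the acceptance script mirrors these sizes.
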