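# actipair

Paired analysis of physical activity measured by a consumer wearable step
tracker and by questionnaire self-report, and of how each relates to body
mass index (BMI).

Consumer trackers report minute-by-minute step counts; the IPAQ short form
asks people to recall, for the last 7 days, how many days and minutes per
day they were vigorously active, moderately active, and walking, plus
sitting time.  `actipair` processes both sources into unit-matched weekly
measures over the *same* 7 days, quantifies their agreement, and compares
their strength as predictors of BMI.  Because self-report carries recall
error, its regression coefficient is attenuated toward zero relative to a
less noisy device measure (regression dilution) — the package's statistics
and its synthetic cohort generator are built around testing exactly that
mechanism.

## What it computes

**Device processing** (`actipair.steps`): minutes with more than 200 steps
are recoded missing; nonwear is any run of ≥120 contiguous zero-step
minutes; remaining minutes are classed by cadence — sedentary 0–9,
walking 10–100, moderate 101–130, vigorous 131–200 steps/min.  A day is
adequate with ≥10 h of wear; a week of 7 adequate days yields steps/d and
weekly time per intensity class.

**Self-report scoring** (`actipair.ipaq`): IPAQ protocol cleaning
(episodes <10 min/day → 0; categories truncated at 180 min/day; responses
with >960 summed min/day invalid), then weekly minutes per intensity
(days × min/day) and overall activity

```
MET-h/wk = 3.3·h_walk + 4.0·h_mod + 8.0·h_vig
```

**Pairing** (`actipair.cohort`): an *activity observation* is a 7-day
recall window whose same 7 days have adequate device data.  BMI is merged
from self-reported anthropometry (weights and BMI averaged within ±90 d,
heights within ±365 d of the window midpoint; calculated and reported BMI
merged by median), covariates from the closest questionnaire within
±365 d.

**Statistics** (`actipair.stats`): Spearman correlations and Wilcoxon
matched-pairs tests (exact, midranked ties, for n ≤ 25) for agreement; a
Cuzick rank test for BMI trend across activity categories; least-squares
regressions of BMI on each activity measure with cluster-robust sandwich
errors grouped by participant,

```
V̂ = c · (X'X)⁻¹ (Σ_g X_g'û_g û_g'X_g) (X'X)⁻¹,   c = G/(G−1) · (N−1)/(N−K)
```

fit as 12 separate + 6 combined (device + self-report head-to-head) models
at three cumulative adjustment tiers, in natural and per-SD units.  Device
and self-report coefficients from separate models are compared by a Wald
test on a stacked system sharing the participant-level cluster covariance.

**Synthetic cohorts** (`actipair.simulate`): bout-structured minute traces
with nonwear gaps and artifact minutes, recall-biased IPAQ responses
(walking and sitting under-reported, moderate and vigorous over-reported),
Table-1-style covariates, and BMI generated from configured per-intensity
effects — so every stage is testable without any external data.

## Worked example

```
python examples/05_bmi_models.py
```

```
fitted 18 model families (6 measure pairs x 3 tiers)

vigorous activity (h/wk), fully adjusted, kg/m2 per h/wk:
          model source   beta  ci_lower  ci_upper  p_value  wald_p_fitbit_vs_ipaq
separate_fitbit fitbit -1.235    -1.870    -0.600    0.000                  0.007
  separate_ipaq   ipaq -0.541    -0.886    -0.196    0.002                  0.007
       combined fitbit -1.066    -1.903    -0.229    0.013                  0.138
       combined   ipaq -0.150    -0.634     0.335    0.545                  0.138
```

On this synthetic cohort of 400 participants, an extra hour/week of
device-measured vigorous activity is associated with a 1.24 kg/m² lower
BMI, versus 0.54 for the self-reported analogue (Wald p = 0.007 for the
difference); in the head-to-head combined model the device measure carries
the association and the self-report adds nothing — the attenuation pattern
the generator encodes.  The other examples walk through minute processing
(`01`), IPAQ scoring (`02`), cohort assembly (`03`), and the agreement
suite (`04`).

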