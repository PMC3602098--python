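# Methods

## Study design being modelled

A fixed cohort is observed over 39 calendar months anchored on an index
date: a 36-month prevalence (lookback) span followed by a 3-month incidence
span.  Index dates fall on the first day of a month — as they do when a
registry records only the diagnosis month, or when a sham date is placed at
the start of the 37th month of enrollment — and every patient has at least
36 months of continuous eligibility before the index date, so claim capture
is complete over the whole span.  All date arithmetic is calendar-month
based; because index dates are first-of-month, offsets such as
"index − L months" are exact, and no 30-day pseudo-month is ever used.

## Condition ascertainment

Conditions are identified from ICD-9-CM diagnosis codes using a fixed
12-condition codebook (cerebrovascular disease, congestive heart failure,
COPD, depression, diabetes, hip fracture, hypertension, liver disease,
myocardial infarction, osteoarthritis, osteoporosis, renal disease).
Matching semantics:

- codes are compared dotless and case-folded (`250.00` ≡ `25000`);
- a plain or wildcarded entry is a *prefix* pattern: `496` and `250.xx`
  match any more-specific descendant, because claims carry variable coding
  specificity; an `x` wildcard drops a position and never acts as a
  single-character matcher;
- a range `A-B` matches a code whose decimal-extended value lies in
  `[A, B]` inclusive, the upper bound covering its own descendants
  (`430-437.1` includes `4370` and `43710` but not `4372`);
- V/E codes order within their letter family only.

The test suite checks the string-based matcher against a fully numeric
interval oracle over every 3–5 digit code (000–99999 and the V family).
Code lists overlap by construction (hypertensive renal disease `403.x` is
both hypertension and renal disease); a claim may therefore count toward
several conditions.

Within a window, a condition is **present** if it has (rule A) at least one
matching inpatient claim, counted at first occurrence, or (rule B) two
matching non-inpatient claims at least 30 days apart, onset at the first.
Decisions that were genuinely open, fixed as follows:

- "at least 30 days apart" is inclusive of exactly 30;
- outpatient-facility and physician claims are *pooled* for rule B (a pair
  may mix the two settings); `pair_pooling="per_setting"` restricts pairs
  to a single setting for sensitivity analysis;
- an inpatient claim does not substitute for a pair member
  (`mixed_rule=True` allows it, off by default);
- windows are half-open `[start, end)`: a claim dated on the index day is
  post-index, since diagnosis-day workup belongs to the incidence period;
- presence is evaluated *independently* per window, so a 30-day pair
  straddling the index date qualifies in neither period.  Whether the
  original design confined pairs to one window is not documented; the
  independent evaluation is the only operationalization consistent with
  nested incident sets (sensitivity ≡ 1), and the straddling consequence
  is covered by an explicit test.
- skilled-nursing, home-health and DME claims, when present in input, map
  to the outpatient-facility setting so the single-claim rule is never
  applied to them.

## Classification and metrics

For lookback L ∈ {6, 12, 18, 24, 30, 36} months, each patient × condition
is assigned to `both`, `prevalence_only`, `incidence_only` or `neither`.
Per condition and L, with I = |incidence_only| and D = |neither|:

- incidence proportion = 1000·I/(I+D) — prevalent patients are excluded
  from the risk set;
- prevalence proportion = 1000·(|both|+|prevalence_only|)/N, computed at
  each row's own L (the gold-standard row is the usual period-prevalence);
- against the gold standard L\* (a parameter, default 36, required to be in
  the grid): FP = incident at L but not at L\*; false positive fraction
  FPF = |FP| / (|both@L\*|+|prevalence_only@L\*|); percent of incident cases
  that are false positives = |FP|/I(L); sensitivity = |TP|/I(L\*) (= 1 by
  construction); specificity = (N−I(L))/(N−I(L\*)); PPV = |TP|/I(L).

Undefined ratios (zero denominators, e.g. FPF on a cohort where nothing is
identified in the gold window) propagate as missing values, never 0.

A caution on monotonicity: the incident *set* at a shorter L always contains
the incident set at a longer L — that is a theorem, and with it FPF(L\*)=0
and non-increasing specificity.  The incidence *proportion* I/(I+D) is not
mathematically monotone in L: if I is unchanged over a step while a longer
lookback still converts `neither` patients to `prevalence_only`, the
denominator shrinks and the proportion rises slightly with L.  The familiar
monotone-rising-incidence-as-L-shrinks picture is an empirical property of
cohorts in which false-positive inflation dominates, and is verified here
at cohort scale as a stochastic check; a unit test constructs the
three-patient counterexample explicitly.

## Synthetic cohorts

Real linked registry/Medicare claims are access-restricted, so cohorts are
simulated with known ground truth.  Per condition, with defaults chosen
once as field-realistic values:

| parameter | meaning | default |
|---|---|---|
| `prevalence` π | P(condition pre-dates the window) | per condition, 0.003–0.32, following published per-1,000 prevalence proportions of the 12 conditions |
| `onset_hazard` h | new-onset hazard, per month, over the 39-month span | 0.0005–0.004 |
| `inpatient_rate` λ_in | Poisson inpatient claims/month once present | 0.005–0.03 |
| `outpatient_rate` λ_out | Poisson non-inpatient claims/month, split evenly between outpatient-facility and physician | 0.10–0.30 |
| `detection_bias` β | intensity multiplier inside the bias window | 3.0 (indexed style), 1.0 (sham) |
| `bias_window_months` | pre-index extent of the bias window (cohort-level; bias always covers the incidence period) | 3 (indexed), 0 (sham) |

Claim and onset times are drawn in continuous index-relative months on
[−36, 3) and mapped to calendar days month-by-month (the fractional part
picks the day within the month).  Month boundaries in simulation time
therefore coincide with calendar-month window boundaries, so an L-month
window contains a Poisson(λ·L) count exactly and the closed-form oracles
are exact rather than 30.44-day approximations:

- `expected_miss_probability(λ, L) = exp(−λL)`;
- under π=1, h=0, λ_out=0 (inpatient-only, single-claim detection) with
  bias confined to the incidence window,
  `E[FPF](L) = (1−e^{−βλ·inc})·(e^{−λL}−e^{−λL*})/(1−e^{−λL*})`,
  recovered by the full pipeline at n=100,000 within 3 Monte-Carlo SEs.

Claim codes are sampled uniformly from concrete member codes of the
condition's patterns; since matching is set-based, the choice is
statistically inert (asserted by a remapping test).  Ground truth stores
`prevalent` (onset before the index, including onsets during the lookback
span; baseline-prevalent onsets get the sentinel date eligibility−1 day),
`incident` (onset in the incidence window) or `absent`.

What the generator does **not** emulate: correlated comorbidity onset,
death/competing risks (cohorts are fully observed, as in the modelled
design), seasonal or provider-driven claim patterns, realistic billing
volumes, or eligibility gaps.  Passing tests therefore validate the
classification arithmetic and the qualitative misclassification mechanics,
not the calibration of any real population; the default parameters land
prevalence in realistic ranges but are illustrative, not estimates.

## Problem sizes and numerical choices

The validation suite uses cohorts scaled to keep each check sharp at
desk scale: exact set-inclusion (sensitivity ≡ 1) at n=5,000; partition and
monotonicity invariants over 100 random n=40 cohorts; brute-force oracle
equivalence over 500 random cohorts of ≤50 patients and ≤8 claims each;
analytic FPF recovery at n=100,000; and the detection-bias contrast at
n=20,000 per cohort, where the pooled false positive fraction of the β=3
cohort exceeds the β=1 cohort at every shortened lookback and the largest
pooled incidence increment falls between L=12 and L=6.  Per-condition
assertions of the bias contrast are limited to the four most prevalent
conditions and to L ∈ {6, 12}: at longer lookbacks the per-condition FPF
rests on single-digit event counts and a sign comparison would be noise.

Ties and degeneracies: two claims on the same day are 0 days apart for the
30-day rule; when the inpatient and pair rules yield the same onset date,
the basis is recorded as inpatient; an empty claim list is simply "not
present"; duplicate claims are allowed and harmless.  The gold standard
must be a member of the L grid, and a metrics summary requires at least two
lookback lengths to contrast.

## Limitations

- The detection algorithm is the standard claims heuristic, not a clinical
  gold standard; the "gold-standard" 36-month lookback is itself a design
  parameter (`gold_L`), and longer gold standards can only shrink the
  incident set — short gold standards understate false positives.
- Rule-out/diagnostic-uncertainty coding, drug- or procedure-based
  ascertainment, and repeat-acute-event logic (e.g. separating a second hip
  fracture from follow-up care) are out of scope.
- ICD-10 and real Medicare file layouts are not supported; inputs are the
  documented patient/claims CSVs.
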