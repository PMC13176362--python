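# Methods

This note documents the model, the synthetic-data generator, the numerical
choices, and the limitations of `strokesim`, in the package's own terms.

## Scope and question

The package compares a *status quo* scenario — national adherence to seven
guideline-recommended stroke-prevention strategies held at its observed
2015–2018 level — against scenarios in which adherence to one or more
strategies is raised (fully, or by a fraction of the remaining gap), for the
U.S. population ≥ 45 years with type 2 diabetes (T2D) and no stroke history.
Outcomes are acute ischemic stroke events, stroke-attributed deaths,
myocardial infarction (MI) events, direct medical costs (2022 USD, payer
perspective), and stroke-related quality-adjusted life-years (QALYs) over a
10-year horizon (a 50-year "lifetime" horizon is available per scenario).

## Cohort generator

The generator emulates a national survey subsample, not any individual-level
real data set.

* **Risk factors.** (age, HbA1c, SBP, TC/HDL ratio, BMI) are drawn from a
  Gaussian copula with configurable marginals (normal or lognormal,
  quantile-truncated to plausibility bounds) and a modest positive
  dependence structure; DBP is drawn from its own marginal.  The age
  marginal's underlying normal is moment-matched (μ = 64.24, σ = 10.69) so
  that after truncation to [45, 100] the realized distribution has the
  target mean 65.1 and SD 9.8 — using the target moments directly would
  bias the truncated mean upward by ≈ 0.5 years.
* **Achievement flags.** Baseline achievement of each of the seven
  strategies is a Bernoulli flag at its configured national proportion
  (defaults: HbA1c 57.6 %, BP 70.7 %, statin 60.0 %, aspirin 7.9 % of the
  eligible, non-smoking 81.1 %, BMI < 25 kg/m² 10.8 %, anticoagulation
  52.4 % of high-risk atrial fibrillation).  For criteria defined by a
  threshold on a continuous factor, the flagged individual's factor is drawn
  from the marginal truncated to the achieving side, by splitting the copula
  uniform at the threshold quantile; this makes the weighted achieved
  proportion converge to the target at the usual √n rate while preserving
  the correlation structure within strata.  Treatment states are assigned
  jointly with the flags (BP achievers carry an ACEi/ARB-containing regimen,
  statin achievers the guideline intensity, etc.) so each criterion is
  meaningful at t = 0.
* **Denominators.** Aspirin and anticoagulation achievement are measured
  among the eligible (the aspirin criterion; atrial fibrillation with
  CHA₂DS₂-VASc ≥ 2); the other five over the whole cohort.  The BMI
  criterion is operationalized as BMI < 25 kg/m², flagged as an
  interpretation since the observed measure could also reflect
  weight-reduction behaviour.
* **Comorbidities.** MI history (12 %), CKD/albuminuria (25 %), family
  history of premature ASCVD (15 %), elevated bleeding risk (10 %) are
  independent Bernoullis; atrial fibrillation prevalence rises with age
  (2/4/8/15 % by decade from 45), reflecting that the survey itself does not
  record it.  Congestive heart failure is not simulated; its CHA₂DS₂-VASc
  point comes from an optional baseline flag defaulting to absent.
* **Weights.** Survey weights are lognormal with coefficient of variation
  0.5 (a typical design-effect magnitude), normalized to sum exactly to the
  configured national total (default 3.7 × 10⁶, configurable because
  published counts for this population vary).  Only point weights are
  modelled; strata/PSU variance estimation is out of scope.
* **Missingness and imputation.** Continuous risk factors are masked
  missing-completely-at-random at configurable rates (defaults 2–10 %).
  Imputations redraw each missing value from the generator's own
  conditional law: the latent copula z-scores of the observed fields give a
  conditional Gaussian for the missing ones, which is mapped back through
  the same flag-truncated marginal.  Averaging imputations over M therefore
  recovers the generator's conditional mean (verified against a
  rejection-sampling oracle).  This is *not* chained-equation imputation of
  real survey data, which is out of scope.

## Treatment policy

Seven strategies, evaluated at the start of every simulated year:

* **Glycemic ladder** 0 lifestyle → 1 one oral agent → 2 two oral agents →
  3 basal insulin → 4 intensive insulin.  Escalate one rung if HbA1c ≥ age
  target (7.0 % under 65, 7.5 % at 65+) and not already on intensive
  insulin; each adopted rung lowers HbA1c by `eff_hba1c_per_rung`
  (default 0.8 %).
* **BP ladder** 0 none → 6 three full-dose drugs in half-dose steps.
  Escalate if SBP/DBP ≥ 140/90 mmHg and below the ladder top; each adopted
  step lowers SBP by 6 mmHg and DBP by 3 mmHg and marks the regimen as
  ACEi/ARB-containing (first-line).
* **Statin intensity**: moderate for all, high for ages 50–70 or ≥ 2 ASCVD
  risk factors, moderate again at ≥ 75; individuals off the recommended
  intensity initiate/switch to it.
* **Aspirin**: initiate if aged 50–70 with ≥ 1 additional major risk factor
  (family history, hypertension, dyslipidemia TC/HDL > 4.5, smoking, CKD)
  and no elevated bleeding risk.  The criterion-based rule is used
  throughout rather than a pooled-cohort absolute-risk cut-off; the two
  published descriptions of the enhancement conflict, and the
  criterion-based version is the one stated with the scenario definitions.
* **Smoking cessation**: one-time year-0 referral of smokers to a
  behavioural intervention; attendees quit with probability 0.12.  No
  relapse is modelled.
* **Weight loss**: one-time year-0 program for BMI > 25 kg/m²; participants
  lose 5 % of body weight.  No regain beyond natural BMI drift.
* **Anticoagulation**: start a NOAC for atrial fibrillation with
  CHA₂DS₂-VASc ≥ 2 and no current anticoagulant.  Baseline warfarin users
  are left unchanged by enhancement.

Adoption of each recommendation is an independent Bernoulli with the
strategy's adherence probability.  *Status-quo adherence* is calibrated by
bisection so that one simulated year (recommend → adopt → drift) maintains
the cohort's own realized baseline achievement proportion.  Calibrating to
the cohort's realized proportion rather than the national target separates
what adherence must offset (drift erosion) from finite-sample noise in the
generated cohort; with fixed adoption uniforms the achieved proportion is a
nondecreasing step function of adherence, so bisection is exact to the step
resolution.  Enhancement sets adherence to 1.0, or to
a + f·(1 − a) for partial implementation with improvement fraction f.

## Disease engine

States: stroke-free → acute stroke (event year) → post-stroke, with two
absorbing death states (stroke-attributed, other-cause).  Each year, after
treatment and drift, cause-specific hazards are computed as products:

* stroke: baseline hazard (0.009/yr at age 65, female, log-linear age slope
  0.065/yr, male excess ×1.25) × recurrence multiplier 2.5 in acute/post
  states × atrial-fibrillation excess ×2.9 × hazard-ratio terms
  `hr^((ref − x)/unit)` for HbA1c (0.92 per 1 % decrease), SBP (0.80 per
  10 mmHg), TC/HDL (0.88 per unit), BMI (0.985 per kg/m²) × smoking ×1.9 ×
  treatment relative-risk reductions (aspirin 0.10; NOAC 0.64 and warfarin
  0.60, atrial fibrillation only; statin 0.15 beyond the lipid pathway).
* MI: analogous products with its own baseline, age slope, history
  multiplier, hazard ratios, smoking ×1.8, and statin RRR 0.25.
* other-cause death: Gompertz life table (0.011/yr at 65, shape 0.092/yr,
  male excess) × T2D multiplier 1.6.
* stroke-attributed death: acute case fatality 0.20 at the event, plus a
  0.045/yr excess hazard in post-stroke states.

Hazard ratios are defined per *decrease* of their unit (the convention the
sensitivity-analysis parameters use), so the hazard multiplier is
`hr^((ref − x)/unit)`; reference levels are HbA1c 7 %, SBP 140 mmHg, TC/HDL
4, BMI 27.  Hazards convert to a yearly event probability by the
competing-risk exponential form P(event) = 1 − e^(−H), with the cause drawn
with probability h_i/H — at most one transition event per individual-year,
consistent with the yearly simulation interval.  MI events are nonfatal in
the engine (fatal coronary disease is folded into the other-cause channel);
they set MI history, add an event cost, and a chronic utility decrement.
Severe hypoglycemia on insulin is a Poisson count per year (0.3 on basal,
2.0 on intensive) feeding disutility only.

Within-year ordering is fixed: treat → drift/age → events → accrual.
Individuals dying within a year accrue that year's medication and event
costs plus a one-time death cost, and zero utility for the death year; no
half-cycle correction is applied.

The smoking hazard multipliers are a deliberate addition to the risk-factor
hazard-ratio set: without a smoking pathway the cessation scenario would
carry costs and no health effect, contradicting the known epidemiology it
is meant to represent.

## Randomness and pairing

All stochastic decisions in a replicate come from a single Philox-seeded
array of uniforms keyed by (master seed, imputation, replicate), with one
row per individual and a fixed column per decision slot (seven adherence
slots, quit success, event occurrence, cause, case fatality, hypoglycemia).
Because slots are positional, every scenario consumes identical draws:
scenario contrasts are exactly paired (a scenario whose adherence equals the
status quo reproduces it bit-for-bit), which both removes Monte-Carlo noise
from null contrasts and tightens uncertainty intervals (verified against
independently seeded runs).  The Poisson hypoglycemia count is drawn by
inverse CDF from its slot so it stays inside the common-random-number block.

## Economics

Per-year costs: medication costs by treatment state after adoption
(glycemic rungs $180–$8,200/yr, with a reduced-insulin-price variant
$1,500/$2,900 for the basal/intensive rungs; BP $120 per half-dose step;
statin $150/$290; aspirin $15; NOAC $5,400; warfarin $600 incl. monitoring),
one-time program costs (smoking $600, weight $700 per attendee), event
costs (acute stroke $22,000; MI $25,000), chronic post-stroke care
$12,000/yr, and a $14,000 death cost.  Utilities: baseline 0.85 with
decrements 0.30 (acute stroke year), 0.15 (post-stroke), 0.05 (post-MI),
0.02/0.05 (basal/intensive insulin burden), 0.005 per hypoglycemia episode,
floored at zero.  QALYs are accrued with all configured decrements
("stroke-related" outputs therefore include survival and utility effects of
MI prevention, which is what makes statin enhancement valuable).

Both costs and QALYs are discounted at 3 %/yr with t = 0 for the first
simulation year.  National totals are person-level discounted outcomes ×
survey weight, summed; report tables round to the printed precisions
(events to 0.1 thousand, costs to $0.1 billion, QALYs/NHB to the nearest
thousand).  ICER = ΔCost/ΔQALY with dominance handling: cost-saving
(ΔCost < 0, ΔQALY > 0) and dominated (ΔCost > 0, ΔQALY < 0) carry no ratio;
ΔQALY = 0 is undefined and reported "NA".  Classification: cost-saving;
ratio < $50,000 highly cost-effective; < $100,000 cost-effective; otherwise
not cost-effective (dominated and undefined map to not cost-effective so
the classification is total).  NHB = ΔQALY − ΔCost/λ at λ = $100,000/QALY,
a value verified exactly against the published combined-scenario row.
95 % uncertainty intervals are the 2.5th/97.5th percentiles (linear
interpolation) of the paired per-(imputation, replicate) deltas, pooled
across imputations; how the original analysis combined imputation- and
replicate-level variability is unspecified, so the pooled-percentile choice
is documented here.

## Scenario catalog and sensitivity analyses

Eleven scenarios: status quo, seven single-strategy enhancements, two
combination scenarios, and all-seven.  Combination membership is
config-declared (defaults: combo 1 = {BP, statin, aspirin, smoking},
combo 2 adds weight loss — the published single-strategy findings) so the
catalog is static and testable; `derive_combos` optionally recomputes
membership from single-strategy ICERs.  One-way sensitivity analysis
re-runs the full comparison with any registry parameter at its low/high
bound (efficacy defaults: hr_hba1c, hr_sbp, hr_lipid, rrr_aspirin,
rrr_noac), plus the reduced-insulin-price cost variant; partial
implementation (f = 0.25, 0.5) and the 50-year horizon are scenario
options.

## Problem sizes and defaults

Desk-scale defaults: n = 1,232 individuals (the emulated cohort size),
M = 10 imputations × R = 50 replicates, 11 scenarios, 10-year horizon —
a full comparison runs in about two minutes on one core.  The original
design (M = 100 × R = 1,000) is reachable by configuration.  Generator
checks use n = 5,000 (proportions) and n = 20,000 (moments); engine oracle
checks use 10⁵ individuals.

## What passing tests do and do not show

The synthetic cohort reproduces configured *marginal* compositions and
achievement proportions; it does not reproduce the true joint distribution
of a real survey (its dependence structure is an assumed copula, its
missingness is MCAR, and its comorbidity flags are independent), so
agreement on synthetic data demonstrates correctness of the machinery, not
epidemiological validity of any particular projection.  Because the
original full parameterization (hazards, costs, utilities) is not public,
national projections from the default registry are indicative only; the
quantities reproduced exactly are the internal arithmetic identities of the
published table (NHB, dominance classification) and the cohort/calibration
quantities the generator is configured to.  Known limitations: yearly time
step (no rapid titration), nonfatal MI, no bleeding-event modelling for
antithrombotics beyond the eligibility flag, no newer antihyperglycemic or
weight-loss therapies, and no system-level intervention costs.
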