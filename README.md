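# strokesim

Microsimulation cost-effectiveness analysis of guideline-recommended primary
stroke-prevention strategies in U.S. adults ≥ 45 years with type 2 diabetes
(T2D).

Stroke is a leading, and expensive, complication of T2D, yet implementation
of the prevention strategies recommended by diabetes and stroke guidelines —
glycemic control, blood-pressure (BP) control, statin therapy,
primary-prevention aspirin, smoking cessation, weight reduction, and
anticoagulation for high-risk atrial fibrillation — remains far from
complete.  `strokesim` asks the resource-allocation question: *if adherence
to each strategy (alone or in combination) were raised from its observed
national level toward full implementation, what would happen to stroke
events, stroke deaths, direct medical costs, and quality-adjusted life-years
(QALYs) over ten years, and which strategies are the best buys?*

The package is aimed at health-economics and epidemiological modellers who
want a transparent, fully scriptable version of this analysis: every hazard,
cost, and utility is a named registry entry with uncertainty bounds, and
every pipeline stage is a plain Python function.

## The model

* **Cohort.** A survey-weighted synthetic population emulating the national
  T2D subsample without stroke history (default n = 1,232; mean age 65.1,
  SD 9.8; 55.8 % male), with correlated risk factors (HbA1c, SBP/DBP,
  total-cholesterol/HDL ratio, BMI) from a Gaussian copula, comorbidities,
  baseline treatment states, and per-person weights summing to the national
  population represented.  Baseline achievement of each of the seven
  strategies is generated at its observed national proportion (e.g. 70.7 %
  BP control, 7.9 % aspirin among the eligible).  Missing risk-factor values
  are masked completely at random and multiply imputed from the generator's
  conditional model.
* **Annual cycle.** Each year: the treatment module recommends escalations
  (antihyperglycemic and antihypertensive ladders, statin intensity,
  aspirin, one-time smoking-cessation referral and weight-loss program, NOAC
  for atrial fibrillation with CHA₂DS₂-VASc ≥ 2); individuals adopt with
  per-strategy adherence probabilities; risk factors drift with age; then a
  competing-risk draw among stroke, myocardial infarction (MI), other-cause
  death, and post-stroke death with P(event) = 1 − e^(−H) and cause
  probabilities h_i/H.  Cause-specific hazards are products of baseline
  age–sex hazards, per-unit hazard ratios (e.g. hr_sbp per 10 mmHg), and
  treatment relative-risk reductions.
* **Economics.**  Costs (2022 USD, payer perspective) and utilities accrue
  per person-year and are discounted at 3 % (first year undiscounted).
  Scenario contrasts vs the status quo give incremental cost-effectiveness
  ratios with dominance classification, and net health benefit
  NHB = ΔQALY − ΔCost/λ at λ = $100,000/QALY.
* **Design.**  Status-quo adherence is calibrated so the simulated
  population maintains its baseline achievement proportions; scenarios are
  run over M imputations × R replicates with common random numbers, so every
  incremental outcome is an exactly paired contrast.

Because the source analysis's full parameterization is not public, the
shipped registry (`strokesim/data/default_registry.yaml`, version
`2022-usd-1`) carries plausible literature-order values with low/high
bounds; swap in your own file to reparameterize everything.

## Worked example

```python
import strokesim as ss

registry   = ss.default_registry()
guidelines = ss.GuidelineSpec()
config     = ss.PopulationConfig(n=1232)

pop      = ss.generate_population(config, seed=1, spec=guidelines)
imputed  = ss.apply_missingness_and_impute(pop, config, M=2, seed=1, spec=guidelines)
adherence = ss.calibrate_status_quo(pop, config, guidelines, registry, seed=1)

catalog = ss.build_catalog()                       # status quo + 10 scenarios
result  = ss.run(imputed, catalog, registry, guidelines, adherence, R=10, seed=1)
table   = ss.results_table(ss.compare_all(result, catalog))
print(table[["scenario", "strokes_averted_thousands",
             "incremental_cost_billions", "nhb_thousands", "icer"]])
```

which prints (desk scale, M = 2 × R = 10):

```
              scenario  strokes_averted_thousands  incremental_cost_billions  nhb_thousands        icer
         hba1c_control                       15.7                       35.1           -571          NA
            bp_control                       42.7                       -1.3             46 Cost Saving
      statin_treatment                       22.5                       -0.5             60 Cost Saving
     aspirin_treatment                       31.9                       -1.1             50 Cost Saving
     smoking_cessation                       11.4                       -0.2             14 Cost Saving
           weight_loss                       13.1                        1.7            -15     830,407
        noac_treatment                       32.4                        2.7              7      80,101
multiple_preventions_1                      101.5                       -2.7            158 Cost Saving
multiple_preventions_2                      114.0                       -0.8            152 Cost Saving
       all_preventions                      161.0                       37.0           -444          NA
```

Reading the output: enhanced BP control would avert ~42,700 strokes
nationally over ten years, save ~$1.3 billion, and add ~46,000 QALYs of net
health benefit, so it is cost-saving; enhanced glycemic control averts
strokes but its insulin costs and disutilities dominate, so the combined
"all preventions" scenario also loses net health.  The incremental column
values are national totals (person-level outcomes × survey weights); `NA`
marks dominated scenarios with no meaningful ratio.

The same pipeline is scriptable from the shell:

```sh
strokesim calibrate --seed 1 --out adherence.yaml
strokesim simulate  --seed 1 --outdir results/
strokesim owsa      --seed 1 --outdir results/   # one-way sensitivity analysis
```

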