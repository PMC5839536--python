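# healthchecksim

An individual-level microsimulation of England's NHS Health Check programme —
the universal cardiovascular risk assessment offered every five years to
adults aged 40–74 without diagnosed diabetes, cardiovascular disease or
hypertension. The package is for epidemiologists and health-policy modellers
who want a fully synthetic, reproducible re-implementation of this class of
screening-programme model: every input the original relied on (restricted
survey microdata, longitudinal panel data, routine disease statistics) is
replaced by a tested synthetic generator, so the whole pipeline runs and is
verifiable end to end on any machine.

## What it models

A closed cohort aged 40–45 is simulated in annual cycles to age 100 under two
arms that share one set of random numbers:

* a **programme arm**, in which eligible individuals are offered a health
  check with annual probability 0.197 (≈ once per five years), attend
  according to a covariate-dependent uptake model, and may be started on one
  or more of four interventions — statins, antihypertensives, smoking-
  cessation referral, weight management — with programme-attributable
  initiation probabilities, imperfect adherence and annual discontinuation;
* a **counterfactual arm** with no systematic programme (routine care is
  implicit in the background risk-factor trajectories).

Risk factors evolve by nonparametric matching to a longitudinal donor panel:
each person is re-matched every year to the k = 10 nearest donors (exact
match on sex and smoking status, weighted Euclidean distance on age and
current factor levels) and inherits the donor's observed annual change.
Treatment acts as additive offsets on the counterfactual path, e.g. an
adherent woman on statins has total cholesterol TC(t) = TC_cf(t) − 1.16
mmol/L while she remains on treatment.

Disease risk is scored with a Cox-type 10-year CVD score,
`risk = 1 − S₀(10)^exp(βᵀx)`, and a points-based 20-year dementia score.
Scores supply relative ordering; absolute annual hazards are anchored to
age–sex incidence derived from prevalence and cause-specific mortality by a
discrete three-state illness–death solver (well → ill → dead, remission
zero), with case fatality recalibrated for acute first-year mortality
(58%/44% of new IHD is acute MI for men/women, with 32%/30% fatality; 60% of
cerebrovascular events are full strokes) and lung-cancer incidence split
between smokers and non-smokers by the population attributable fraction.
An extra statin hazard ratio is calibrated by bisection so the simulated
5-year event-rate reduction matches a configured trial value.

Outcomes: incident cases prevented (by 80 and 100), premature deaths
prevented (<75, <80), QALYs (EQ-5D-style utilities by age, deprivation and
disease) and life-years, per-head/per-eligible/per-attender/per-check days,
deprivation-quintile equity metrics, scenario deltas (eligibility changes,
+30% uptake variants, 2.5× treatment variants, a combined "maximum
potential"), probabilistic sensitivity analysis with 95% credible intervals,
and value-of-information (SD-if-learnt) parameter rankings.

## Worked example

```python
import healthchecksim as hcs

sim = hcs.build_simulation(n_individuals=20000, seed=1, n_panel=8000)
table = hcs.run_pair("base", "no_programme", master_seed=1, sim=sim)
for k in ("deaths_prevented_under_80", "disease_free_at_80",
          "qaly_total_per_million", "ly_total_per_million",
          "qaly_days_per_head", "ly_days_per_head",
          "pct_ever_attended", "checks_per_head"):
    print(f"{k:45s} {table[k]:10.1f}")
```

prints

```
deaths_prevented_under_80                         1750.0
disease_free_at_80                                3050.0
qaly_total_per_million                           34410.0
ly_total_per_million                             40925.0
qaly_days_per_head                                  12.6
ly_days_per_head                                    14.9
pct_ever_attended                                   86.2
checks_per_head                                      3.0
```

Reading: per million people aged 40–45 at baseline, the simulated programme
prevents 1,750 premature deaths before age 80 and leaves 3,050 more people
alive and free of IHD, stroke, dementia and lung cancer at 80; over the life
of the cohort it adds ~34,000 QALYs and ~41,000 life-years, i.e. 12.6
quality-adjusted days and 14.9 days of survival per head. 86% of the cohort
attend at least one check (3.0 checks per head on average). At n = 20,000 a
single paired run is noisy — credible intervals come from the PSA:

```python
result = hcs.psa("base", "no_programme", master_seed=1, n_runs=100,
                 n_individuals=200000)
print(result.summary())          # mean and 2.5/97.5 percentiles per metric
```

The same comparisons run from the shell:

```bash
healthchecksim simulate --scenario treat_all_2.5 --reference base --n 20000 --seed 1
healthchecksim simulate --list
```

Scale note: synthetic magnitudes are larger than the published programme
estimates (which depend on restricted survey microdata), but signs, orders
of magnitude and scenario orderings agree; see `docs/methods.md`.

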