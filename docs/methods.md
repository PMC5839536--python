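# Methods

## Model structure

The simulation is a discrete-time, individual-level state-transition model
with annual cycles. Each simulated person carries demographics (age, sex,
ethnicity, deprivation quintile, education band), six continuous risk
factors (systolic and diastolic blood pressure, total cholesterol, HDL, BMI,
HbA1c), smoking status, baseline condition flags (treated hypertension,
diabetes), four disease flags (IHD, stroke, dementia, lung cancer, plus a
distinct TIA flag) and a vital status. Two or more policy arms advance in
lockstep over a single stream of per-person uniforms drawn in fixed order
each cycle, so arms with identical policies are byte-identical and paired
differences isolate the programme effect (common random numbers). The
within-year order is: risk-factor advance, health-check process, disease
events and chronic-case deaths, other-cause death. Follow-up ends at death
or age 100 (survivors are censored, not killed).

## Synthetic data in place of restricted sources

Three generators stand in for data the original analysis holds under
restriction; what the tests show therefore concerns the *mechanics* of the
pipeline under controlled conditions, not the real English joint
distributions.

**Baseline cohort.** Categorical attributes are multinomial draws from
survey-matched marginals (50.4% male, 86.1% White, 24.6% current smokers,
…). Continuous factors use a Gaussian copula over log-normal margins with
locations/scales set so means and spreads match the survey table (BMI mean
27.5 kg/m² with 27.1% obese, SBP 122.6 mmHg, TC 5.5 mmol/L, …).
Deprivation shifts current-smoking probability (multiplicative gradient
exp(0.22·(q−3)), renormalised so the overall marginal is preserved exactly)
and the BMI log-location (0.025 per quintile, zero-mean), so equity metrics
are exercised non-trivially. Treated hypertension (4.6%) and diabetes
(3.3%) are logistic in SBP and HbA1c with intercepts solved so realised
prevalence equals the target. What the generator does *not* emulate: the
full HSE joint dependence of deprivation with every factor, ethnic-specific
risk-factor distributions, and incident hypertension/diabetes diagnosis over
follow-up (condition flags are fixed at baseline, so eligibility attrition
is weaker than in reality and more checks are delivered per head — ~3.0
versus the ~1.9 reported from programme data).

**Donor panel.** Person-wave records at biennial spacing: each factor is a
linear age trend plus a stationary AR(1) deviation (per-wave ρ = 0.85,
stationary SD equal to the cross-sectional SD), with per-wave smoking
quit (0.06) and relapse (0.03) transitions. Annual changes are the donor's
biennial change × 0.5; donor smoking transitions apply with probability 0.5
per year. Matching uses exact sex and smoking strata and a weighted
(age-weight 2) standardised Euclidean distance over age and the six factors,
k = 10, uniform choice among the k nearest; re-matching is annual.

**Epidemiology.** Per-disease incidence i(a) = i₀·e^(slope·(a−40)) and
chronic case fatality f(a) = f₀ + f₁·(a−40) are forward-integrated through
the illness–death recurrence together with Gompertz background mortality to
emit internally consistent prevalence and cause-mortality curves plus an
all-cause lifetable (background + modelled causes). Incidence levels are
calibrated — once, by iterated 50,000-person simulation, then frozen — so a
no-programme cohort of one million accumulates ≈355k IHD, 184k stroke, 147k
dementia and 148k lung-cancer diagnoses and ≈405k premature deaths over 60
years, the totals routine English data imply for this cohort; the lifetable
tracks an English shape (q(40) ≈ 1e-3, q(80) ≈ 0.05–0.07, a few percent
surviving to 100).

## Rate derivation

The solver inverts the same discrete recurrence the generator uses: states
counted at cycle start, incident cases arising mid-year with half-year
case-fatality exposure (1 − √(1−f)), background mortality multiplicative and
independent (it cancels from the prevalence ratio). At each age the observed
cause mortality and next-year prevalence give two equations in (i, f),
solved by bounded least squares with a residual tolerance of 1e−8;
infeasible inputs raise an error naming the first infeasible age. Acute
recalibration replaces the incident-year fatality with the acute event-mix
expectation (e.g. men's IHD: 0.58 × 0.32 = 0.1856) and scales the chronic
rate by a per-sex factor solved by Brent's method so cumulative cause deaths
to age 100 are conserved; survivors adopt the scaled chronic rate from the
year after diagnosis. TIAs carry no acute or chronic fatality but mark the
person as having prevalent CVD. The smoker/non-smoker lung-cancer split is
the closed form i_ns = i(1−PAF), i_s = i_ns + PAF·i/p (PAF 0.85; p taken
from the cohort's baseline current-smoking prevalence per sex, so the
mixture identity holds at baseline; ex-smokers use non-smoker rates — a
simplification that understates residual ex-smoker risk).

## Hazards and events

Individual annual hazards are proportional: h_i = incidence(a,s) ·
score_i / mean score(a,s), with the cell mean taken over alive, disease-free
individuals on their *counterfactual* paths (cells under 20 people fall back
to the 5-year band, then the sex mean). This anchors cohort incidence to the
tables while the score orders individuals; treatment then lowers an
individual's hazard relative to that anchor. The CVD score is a reduced
Cox-type set over the available covariates (the published algorithm's extra
covariates — family history, CKD, AF, rheumatoid arthritis — have no
counterpart in the synthetic cohort; a full coefficient file of the same
shape can be substituted). The dementia score is points-based with a
monotone points→risk mapping; its physical-activity component is a
configurable constant (no activity variable exists in the cohort). New CVD
events split IHD/stroke by the cell incidence share, then MI vs other
presentation (0.58/0.44 by sex) and full stroke vs TIA (60:40), with acute
fatality by type (MI 0.32/0.30; stroke 0.07/0.05 under 80, 0.24/0.17 at
80+). The statin hazard ratio (default 0.85) is calibrated to a configured
5-year trial relative risk (default 0.80) by bisection on a paired 5-year
harness that integrates event randomness out analytically (per-individual
cumulative event probabilities), removing Monte-Carlo noise from the
calibration target. Baseline IHD/stroke flags are assigned with probability
proportional to the score, matching table prevalence at ages 40–45; nobody
has dementia or lung cancer at baseline.

## Programme mechanics

Eligibility is the 40–74 window without diabetes, CVD or treated
hypertension (scenario variants widen or shift it); ineligible people in the
age window attend as drop-ins with probability 0.05 per offer and are
treated on the basis of their measured factors. Attendance is a base
per-offer probability times rate ratios by age band, sex, ethnicity,
deprivation, smoking and risk band, normalised so the cohort-mean per-offer
attendance is 0.49 (the rate ratios are plausibility defaults; the source
programme-evaluation coefficients are not public). The optional
state-dependent mode replaces the covariate model with 0.70/0.30 per offer
for previous attenders/non-attenders. Treatment-initiation probabilities
are attender-minus-non-attender differences (statins 2.05%/14.23% by risk
band; antihypertensives 1.54%/2.48%, gated on measured SBP > 140 mmHg;
cessation referral 3.6% of smokers; weight referral 27.5% of BMI ≥ 30).
Initial adherence is 0.50 (statins) / 0.55 (antihypertensives) with 5%
annual discontinuation (absorbing); weight management is attended by 50%;
referred smokers quit with probability 0.146 evaluated one year after the
check, then face the panel-derived annual relapse hazard. Offsets apply
only while active: statins −1.22/−1.16 mmol/L TC and +0.04/+0.036 HDL by
sex; ACE inhibitor −6.29/−4.14 mmHg under age 55, calcium-channel blocker
−7.6/−3.1 (men) or −9.0/−3.5 (women) at 55+; the weight BMI schedule is
(−1.5, −0.9, −0.6, −0.3, 0) over five years. Treatments do not interact;
on discontinuation the treated path snaps back to the counterfactual. BMI
acts on disease only through the risk scores.

## Outcomes

QALYs multiply a baseline utility by age band (0.87 at 40–49 falling to
0.68 at 90+), a deprivation adjustment (1.00→0.95 across quintiles) and
multiplicative disease decrements (IHD 0.88, stroke 0.80, TIA 0.95, dementia
0.55, lung cancer 0.70) — multiplicative combination keeps multimorbidity
utilities positive. The death year contributes half a cycle of person-time;
a new diagnosis takes its decrement from the event year. Premature-death
counts use the recorded event age with no half-cycle. Per-quintile metrics
are per-head within quintile before scaling. The per-million →
England-per-year annualisation multiplies by 0.73. The pipeline reports the
compression-of-morbidity direction automatically
(`morbidity_compression_days` = per-head QALY gain − per-head LY gain).

## Uncertainty

Each parameter with a credible interval gets a beta (probabilities;
concentration solved so the 2.5–97.5 quantile width matches) or normal
(effect sizes) distribution. A PSA samples all parameters jointly per run
(scenario and reference share the draw), re-runs the paired simulation, and
summarises runs by mean and 2.5/97.5 percentiles; study-scale defaults are
100 runs × 200,000 individuals, fully configurable downward for desk-scale
work. Value of information bins the runs on the sorted draws of one
parameter (≈√n bins) and reports √E[Var(Y|θ)] (SD if learnt) and the
between-bin variance fraction; the within/between decomposition is exact on
the sample, so the law of total variance holds by construction. The
run-level CVD-score multiplier is log-normal with 2.5/97.5 quantiles at
0.8/1.2, one draw per run shared by all individuals, applied to the absolute
hazard (a relative multiplier would cancel in the proportional calibration).

## Numerical and design choices

Seeds: every generator and run takes an explicit seed; sub-seeds derive via
`SeedSequence`. Solver tie-breaks: the last age carries the previous age's
case fatality; empty cells inherit band means. HDL is capped at 0.9×TC.
Probabilities pushed past 1 by scenario multipliers are clipped and counted
in a per-run clip report. Rate-table CSVs round-trip losslessly (`%.17g` on
write, `round_trip` parsing on read). Problem sizes in the test-suite:
marginal checks at n = 200,000 (generation only); paired-run properties at
n = 3,000–20,000; the headline run and oracle checks at n = 100,000; statin
calibration at n = 50,000; PSA properties at 30 runs × 1,500.

## Known limitations

* Synthetic programme-effect magnitudes are ~3–4× the published per-million
  estimates, mainly because fixed baseline condition flags understate
  eligibility attrition (more checks per head) and the synthetic cohort's
  risk-score dispersion differs from the survey joint distribution. Signs,
  orders of magnitude and scenario orderings agree.
* The compression-of-morbidity direction (per-head QALY gain exceeding
  per-head life-year gain) is *not* reproduced under the default synthetic
  conditions: the simulated benefit mix is more mortality-weighted (about
  two extra disease-free survivors per premature death prevented, versus
  roughly 3.5 in the published analysis), so the sub-unit utility weighting
  of added life-years dominates the morbidity-avoidance component. The
  pipeline reports the direction rather than assuming it.
* The published equity finding (largest absolute per-head gains in the most
  deprived quintile) is likewise input-dependent; with the default mild
  deprivation gradients and lower deprived attendance, gains are flat to
  mildly pro-affluent. The equity machinery itself is exercised by
  construction tests (symmetric cohorts show no gradient; a deprived-only
  uptake boost moves only the deprived quintile).
* No costs, no discounting, no alcohol interventions, no COPD or non-lung
  cancers, no treatment harms, no recurrent-event modelling; dementia and
  lung-cancer case fatality are not recalibrated for acute mortality.
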