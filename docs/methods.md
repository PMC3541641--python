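# Methods

This note documents the model underlying `petdes`: what is simulated, the
assumptions behind every parameter block, the numerical machinery, and the
places where the published evidence base is silent and a design choice had to
be made. Defaults live in `petdes.config.ScenarioConfig`; every value named
here can be overridden from a YAML/JSON scenario file or by dotted path.

## 1. Population

Patients enter at their first physician visit for cognitive complaints and
are assumed to have some form of (pre)dementia; complaints with purely
psychiatric or other medical causes are out of scope. The baseline mixture
reproduces the confirmed-diagnosis distribution of the source cohort:

* phase: 68% dementia, 32% predementia;
* dementia causes: 67% AD or mixed AD, 28% vascular dementia (VaD), 5%
  other (Lewy body, frontotemporal, mixed non-AD);
* predementia causes: 65% prodromal AD, 35% nonprodromal (these latter carry
  a latent non-AD dementia type, drawn from the dementia-phase non-AD mix,
  that becomes their cause on conversion);
* age ~ Normal(78, 7) predementia / Normal(82, 7) dementia, truncated to
  [55, 100] (55 is the life-table basis of the mortality model); 30% male.

Several covariates required by the fitted equations are not published with
the model inputs and are set to plausible values for an elderly US veteran
population, all config-overridable and rangeable in sensitivity analysis:
sub-splits within AD-type (25% mixed) and within the "other" group
(40/30/30 LBD/FTD/mixed), comorbidity prevalences (CKD 10%, cerebrovascular
disease 15%, diabetes 25%, hypertension 60%, stroke 10%), psychotropic
medication use 20%, race mix 85/10/5 white/black/other, caregiver age =
patient age − 3, caregiver sex opposite the patient, 70% living with a
caregiver.

Baseline scale scores are clamped normals with phase-specific means matching
the reported simulated baselines (predementia MMSE 27.5, NPI 2.5, ADL = IADL
10.1; dementia MMSE 21.9, NPI 16.3, ADL 29.7, IADL 29.1). The dispersions
are not published; defaults are MMSE SD 4 (dementia) and 1.5 (predementia),
NPI SD 6/2, ADL and IADL SD 8/4. The dementia MMSE sampler was chosen so
that, as reported for the source chart review, over 60% of AD patients start
above MMSE 20; the tighter predementia SD keeps the clamp at 30 from biasing
the mean (with SD 4 the clamped mean would fall ~0.7 points below target).
Scale maxima: MMSE 30, NPI 144, ADL 54, IADL 56 (higher = worse for
NPI/ADL/IADL in this model's convention, consistent with the caregiver
utility equation's negative coefficients on them).

## 2. Severity

Five MMSE bands (NICE-style banding; the exact cut points are not printed in
the source and are config-overridable): mild 21-30, mildly moderate 15-20,
moderate 10-14, moderately severe 5-9, severe 0-4. Diagnostic accuracy
tables collapse to two columns: "mild" vs all other bands.

## 3. Diagnosis

Usual care assigns one algorithm per patient (clinical only 73%, MRI-MTA 8%,
CT-MTA 19%); the comparator arm always scans with florbetaben PET (90/90
accuracy in both severity columns). The AD label is drawn against the true
cause with the algorithm's sensitivity/specificity evaluated **at the
severity band reached by the confirmation date** — disease progresses during
the work-up, which is what pushes usual-care false negatives above the naive
mild-band calculation.

Time to confirmation is a lognormal AFT draw from the cause-matched
equation; the PET arm multiplies the same draw by (1 − reduction), default
reduction 50%. Patients dying — or converting to dementia — before their
confirmation date never receive a scan or a diagnosis label.

Design choices where the source is silent:

* **Re-diagnosis of false negatives.** Misdiagnosed AD-type patients may be
  correctly re-labelled later: an exponential delay with mean 24 months
  (no observed value; ranged in DSA), after which the label flips to truth
  and, if never treated, usual-care AD-positive uptake (77%) applies once.
  False positives are never re-labelled (non-AD patients with a negative
  result are taken as correctly confirmed).
* **Conversion during the work-up.** Such patients are confirmed at the
  originally drawn date with a correct dementia-type label, no scan, and
  usual-care uptake probabilities in both arms. This affects only a few
  percent of predementia patients and keeps the arms comparable.

## 4. Treatment

Uptake at confirmation: PET arm treats exactly the scan-positives;
usual-care dementia patients treat with probability 77% (AD-positive label)
or 67% (non-AD label), predementia patients 28% irrespective of truth.
Untreated usual-care patients may still initiate later via lognormal AFT
initiation equations. Scan-negative patients in the PET arm initiate only
through the re-diagnosis pathway. One treatment episode per patient; no
re-initiation after discontinuation.

Persistence is Weibull AFT (dementia equation keyed on time-to-diagnosis;
predementia equation carries a conversion covariate, so a predementia
starter's clock continues with the converted term after conversion). The PET
arm halves the discontinuation hazard; under the default σ-interpretation
this stretches every quantile by 2^σ (a plain doubling of the sampled time
is available as a config switch).

Stopping rules: dementia treatment stops at MMSE ≤ 10 (and cannot start
below it); predementia treatment is capped at 5 years if unconverted.

Clinical benefit is restricted to AD-type pathology: the conversion hazard
ratio (0.5) applies only to treated prodromal AD; the progression-equation
treatment terms, the MMSE offset and the institutionalization treatment
covariate apply only to treated AD/mixed-AD patients. For everyone else
treatment is a drug cost. Drug mixes by label (AD+ 63/25/5/7, non-AD
66/9/4/21, predementia 76/6/1/17 across donepezil/galantamine/rivastigmine/
memantine) price the episode.

## 5. Progression

Dementia-phase cognition declines by a fitted annual rate built on a
piecewise-linear spline of the previous MMSE (knots at 10 and 20: PM1 =
min(m,10), PM2 = clamp(m−10,0,10), PM3 = clamp(m−20,0,10) — the published
footnote names the partition without printing the basis; the knots are
config-overridable), the previous decline rate, and baseline age. FTD adds
4.4 points/year. AD-type patients additionally progress on NPI, ADL and IADL
through fitted linear equations sharing covariates with cognition; non-AD
dementia progresses on MMSE only. Predementia patients hold baseline scores
until conversion, which applies a one-time 2-point MMSE step (assumption,
ranged in DSA) and starts dementia dynamics.

Numerical conventions:

* scores re-evaluate every 6 months and at every event, with annual rates
  pro-rated linearly inside a cycle, and clamp to their scale ranges;
* the behaviour equation's duplicated baseline-NPI term (a typographical
  ambiguity in the printed equation: "−0.59 NPI_base − 0.59 NPI Weeks") is
  resolved to a single −0.59·NPI_base main effect; the interaction reading
  is numerically explosive on a 0-144 scale;
* the Weeks covariate caps at 52: continued treatment after one year is
  maintenance-only, and an uncapped linear Weeks term would dominate the
  equations over a lifetime horizon;
* the published MMSE equation has no treatment term; the symptomatic effect
  on cognition is a configurable offset (default 0.5 points/year slower
  decline on treatment, AD-type only), documented as an assumption and
  ranged in DSA;
* per-scale random intercepts δᵢ ~ Normal(0, σ) are supported with default
  σ = 0 (no published variance).

## 6. Institutionalization, mortality, horizon

Institutionalization is Weibull AFT: the dementia equation responds to age,
dementia type, time-to-confirmed-diagnosis (every 100-day shortening of the
work-up lowers the risk scale by ~10%, the model's main cost lever) and
dementia treatment (+1.079 on the log scale); the predementia equation uses
age only, switching to the dementia equation at conversion with the pending
time re-solved conditionally.

Mortality is Gompertz in current age from sex-specific life-table fits
(male scale −9.697/shape 0.087; female −10.787/0.097), multiplied by stage
hazard ratios (predementia 1.48; AD-type dementia 2.84; non-AD 2.69). Each
patient draws one mortality uniform shared by both arms; at conversion the
hazard switches and the death time is re-solved conditional on survival so
far. Treatment never affects mortality directly — dementia-cohort net
survival is exactly zero by construction — while predementia patients gain
survival through delayed conversion. Horizon: death or age 105.

The cumulative-hazard tracker used for all of this stores the target
−ln U per pending event; every covariate change banks the hazard consumed
under the outgoing curve and re-solves the time under the incoming one, so
arm differences reflect parameters, never fresh randomness.

## 7. Economics

Continuous discounting at 3%/year, at event-time resolution (annuity
integrals per piecewise-constant segment, never annual cycles). Cost blocks
(2011 USD): diagnostic work-up rates per year by underlying diagnosis while
the work-up is open; one test cost per add-on test or scan; drug cost per
day on treatment; severity-banded medical and community nonmedical care
during dementia; predementia medical care $5,548/year; institutional care
$373/day replacing community nonmedical care after placement; caregiver time
(2.10 h/day predementia, 2.10-5.10 h/day by dementia severity) valued at
$7.25/h while the patient lives in the community. The "% of additional cost
of care for non-AD relative to AD" rows (VaD 84%, other 37%) are read as
cost_nonAD = fraction × cost_AD — the reading under which non-AD care is
cheaper than AD care, consistent with the cited cost source — with the
(1 + fraction) reading available as a config switch.

Utilities: predementia patients 0.82; dementia patients a fitted regression
on MMSE, NPI, institutionalization and caregiver co-residence (non-AD 0.006
lower), clamped to [0, 1]. Caregiver utility is a fitted regression on
caregiver age/sex and the patient's sex, NPI, ADL, IADL and psychotropic
use. Caregiver time, cost, and QALYs accrue only while the patient is alive
and community-dwelling; the patient-utility equation's institutionalization
decrement takes over after placement. A config flag drops caregiver-time
costs for the payer perspective.

## 8. Experiments

* **Reference case**: 10 replications × 1,000 patients × 2 arms, predementia
  and dementia sub-cohorts reported separately; classification on the CE
  plane with WTP $50,000/QALY (dominant iff QALYs gained and money saved;
  ICERs at the threshold count as acceptable; QALY losses must be strictly
  over-compensated by savings).
* **One-way DSA**: re-runs the reference case at each parameter's bounds
  under common random numbers; named scenario levers (time-reduction 0-75%,
  discontinuation HR 0.5-1.0, conversion effect 25-50%, predementia uptake
  28-100%) plus ±20% on the main unobserved inputs; tornado sorted by net-
  cost swing. A generic 2-D sweep utility covers two-parameter scenarios.
* **PSA**: the published distributional appendix is not available, so
  second-order distributions are a documented design choice: Beta for
  probabilities and utilities (SE = 10% of mean, moment-matched), Gamma for
  costs (SE = 20%), Normal for effect multipliers (SE = 10%); all
  overridable. Each replication draws one parameter set and re-runs both
  arms; outputs are CE-plane points and the acceptability fraction at a
  given WTP.

## 9. What the synthetic cohort does and does not capture

The generator reproduces the *marginal* structure the model was built on —
phase/cause mixture, age and sex composition, baseline severity distribution
— but draws covariates independently within patient (no comorbidity
clustering, no age-severity correlation) and knows nothing about measurement
error or practice effects in MMSE. Tests passing on this cohort demonstrate
that the simulation machinery reproduces its specified event-time
distributions, accuracy arithmetic and accounting identities; they do not
validate the fitted equations against any external patient population.

Dollar and QALY *magnitudes* depend on the unpublished covariate prevalences
and scale dispersions above; the test suite therefore pins signs, dominance
classification and the published calibration quantities (cohort mix,
confusion-matrix shares, analytic event-time summaries, work-up completion,
zero net dementia survival) rather than the dollar figures themselves.

## 10. Known limitations

Single treatment episode per patient (no switching, titration or adverse
events); no scanner capacity constraints or queues; inconclusive scans not
modelled; at most one add-on test per work-up; non-AD false negatives are
assumed correctly confirmed; no inflation adjustment beyond the 2011 cost
year; conversion-time parameterization is ambiguous in the source (the
rate-form default gives a 39-month median against a reported "about 35
months"; the scale-inside-power alternative gives 32 — both implemented,
neither exact).
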