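# petdes

Discrete event simulation of amyloid-PET-aided dementia diagnosis and its
lifetime cost-effectiveness.

`petdes` is an individual-patient microsimulation for people who present to a
physician with suspected dementia, in either the predementia (prodromal) or
dementia phase. It compares two diagnostic strategies from US payer and
societal perspectives:

* **usual diagnostic care** — a work-up under clinical guidelines, possibly
  with one add-on test (MRI/CT of medial temporal atrophy, FDG-PET, SPECT, or
  CSF biomarkers), drawn from an observed usage mix; and
* **usual care plus florbetaben PET** — the same work-up augmented with a
  beta-amyloid tracer scan (sensitivity = specificity = 90% across severity).

Each simulated patient carries a true underlying cause (prodromal AD, AD,
mixed AD, vascular dementia, Lewy body dementia, frontotemporal dementia,
mixed non-AD), and the confirmed AD-positive/negative label is drawn against
that truth from the assigned algorithm's severity-dependent accuracy. The
model then follows the patient for life: treatment uptake, drug mix and
persistence, conversion from predementia, cognition/behaviour/function
progression (MMSE, NPI, ADL, IADL), institutionalization, and death, accruing
discounted costs and QALYs for patient and caregiver.

## Model core

Event times come from fitted parametric survival models evaluated on patient
covariates through accelerated-failure-time (AFT) linear predictors
μ = β₀ + Σ βᵢxᵢ:

* **lognormal AFT** (time to confirmation, delayed treatment initiation):
  T = exp(μ + σZ);
* **Weibull AFT** (treatment discontinuation, institutional care):
  T = exp(μ)·(−ln U)^σ, i.e. S(t) = exp(−(t/e^μ)^{1/σ});
* **Weibull rate form** (conversion to dementia): S(t) = exp(−λt^k) with
  λ = 0.0212/month, k = 0.952;
* **Gompertz mortality**: h(a) = HR·exp(scale + shape·a) from sex-specific
  life-table fits, scaled by disease-stage hazard ratios (1.48 predementia,
  2.84 AD-type dementia, 2.69 non-AD dementia), sampled conditional on the
  current age.

The florbetaben strategy acts through four levers, each config-overridable:
a 50% cut in time to confirmation, 90/90 diagnostic accuracy, scan-driven
treatment uptake (treat iff AD-positive), and a 0.5 hazard ratio on treatment
discontinuation. Treatment halves the conversion hazard for prodromal AD and
slows symptomatic progression for AD-type patients only; for non-AD patients
it is a pure cost.

Both arms of each patient share every random draw (common random numbers),
and pending event times are stored as target cumulative hazards so that
covariate changes (treatment start/stop, conversion) re-solve the event time
conditionally instead of redrawing it.

## Worked example

```python
from petdes import ScenarioConfig, reference_case

cfg = ScenarioConfig()                      # reference-case defaults
res = reference_case(cfg, n=1000, reps=10, seed=42)
for phase in ("predementia", "dementia"):
    co = getattr(res, phase)
    print(f"{phase:12s}  survival {co.usual.survival_years:5.2f} -> "
          f"{co.florbetaben.survival_years:5.2f} y"
          f" | time to dx {co.usual.time_to_dx_months:4.2f} -> "
          f"{co.florbetaben.time_to_dx_months:4.2f} mo"
          f" | net cost ${co.net_cost:,.0f}"
          f" | net QALYs {co.net_qaly:+.3f} | {co.ce.classification}")
```

prints

```
predementia   survival  6.85 ->  6.93 y | time to dx 5.12 -> 2.65 mo | net cost $-7,561 | net QALYs +0.243 | dominant
dementia      survival  4.45 ->  4.45 y | time to dx 5.14 -> 2.74 mo | net cost $-10,986 | net QALYs +0.093 | dominant
```

Reading: over ten replicated 1,000-patient cohorts, the PET arm confirms the
diagnosis about 2.4 months sooner; dementia-cohort survival is identical in
both arms (treatment has no survival effect and the arms share mortality
draws), while predementia patients live slightly longer because treatment
delays conversion to the higher-mortality dementia phase. In both cohorts the
scan strategy gains QALYs and saves money — it *dominates* usual care under
the reference assumptions, mostly through delayed institutionalization.

The command line mirrors this and adds sensitivity analyses:

```bash
petdes simulate --config scenario.yaml --n 1000 --reps 10 --seed 42 --out results/
petdes dsa --n 200 --reps 2 --out results/      # one-way tornado table
petdes psa --reps 1000 --n 100 --out results/   # CE plane + CEAC
```

`scenario.yaml` may override any default, e.g.:

```yaml
diagnostics:
  time_reduction: 0.0          # scan does not shorten the work-up
treatment:
  conversion_risk_reduction: 0.25
costs:
  institutional_per_day: 450.0
```

## Layout

- `src/petdes/cohort.py` — synthetic baseline population
- `src/petdes/parametric_models.py` — equation specs and survival samplers
- `src/petdes/diagnostics.py` — algorithms, accuracy, time to confirmation
- `src/petdes/treatment.py` — uptake, drug mix, persistence, stopping rules
- `src/petdes/progression.py` — MMSE/NPI/ADL/IADL dynamics and severity
- `src/petdes/engine.py` — per-patient event scheduling under CRN
- `src/petdes/economics.py` — discounted costs, utilities, QALYs
- `src/petdes/experiments.py` — reference case, DSA, PSA, CE classification
- `docs/methods.md` — modelling assumptions and numerical choices
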