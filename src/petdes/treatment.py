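"""Dementia treatment: uptake, drug mix, persistence and stopping rules.

Cholinesterase inhibitors and memantine are symptomatic; they slow
progression (via the treatment terms of the progression equations), delay
institutionalization, and — for prodromal AD only — halve the conversion
hazard.  Patients whose true cause is non-AD gain no clinical benefit from
treatment but still incur its drug costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, ScenarioConfig
from .diagnostics import DiagnosisResult, FLORBETABEN
from .parametric_models import linear_predictor

DRUGS = ("donepezil", "galantamine", "rivastigmine", "memantine")


@dataclass
class TreatmentState:
    on_treatment: bool = False
    drug: str = "none"
    start_time: float | None = None
    stop_time: float | None = None
    ever_treated: bool = False
    forced_stop_reason: str = "none"   # none | mmse_floor | max_duration | discontinued

    def start(self, t: float, drug: str) -> None:
        self.on_treatment = True
        self.ever_treated = True
        self.drug = drug
        self.start_time = t
        self.stop_time = None
        self.forced_stop_reason = "none"

    def stop(self, t: float, reason: str) -> None:
        self.on_treatment = False
        self.stop_time = t
        self.forced_stop_reason = reason


def uptake_at_confirmation(diagnosis: DiagnosisResult | None, arm: str, phase: str,
                           config: ScenarioConfig, rng: np.random.Generator) -> bool:
    """Whether treatment starts at the moment the diagnosis is confirmed.

    Florbetaben arm: treat iff the label is AD-positive.  Usual arm: dementia
    patients by label-specific uptake; predementia patients by the
    unconditional predementia uptake.
    """
    tc = config.treatment
    if arm == FLORBETABEN:
        return diagnosis is not None and diagnosis.positive
    if phase == "predementia":
        return rng.uniform() < tc.uptake_usual_predementia
    p = (tc.uptake_usual_ad_positive if diagnosis is not None and diagnosis.positive
         else tc.uptake_usual_nonad)
    return rng.uniform() < p


def delayed_initiation_time(covariates: dict[str, float], phase: str,
                            config: ScenarioConfig, rng: np.random.Generator) -> float:
    """Days from confirmation to treatment initiation for patients untreated
    at confirmation (lognormal AFT)."""
    key = "tti_predementia" if phase == "predementia" else "tti_dementia"
    spec = config.equations[key]
    mu = linear_predictor(spec, covariates)
    z = rng.standard_normal()
    return float(np.exp(mu + spec.dispersion * z))


def discontinuation_time(phase_at_start: str, time_to_dx_days: float, converted: bool,
                         arm: str, config: ScenarioConfig,
                         rng: np.random.Generator) -> float:
    """Days on treatment before discontinuation (Weibull AFT).

    The florbetaben arm halves the discontinuation hazard; under the AFT
    sigma-interpretation that stretches every quantile by ``(1/hr)**sigma``
    (with the config switch, by a plain factor ``1/hr``).

    This is the unconditional draw used for testing and audit; the engine
    itself tracks the same distribution through a cumulative-hazard tracker
    so covariate changes (conversion) re-solve the pending time.
    """
    key = "disc_predementia" if phase_at_start == "predementia" else "disc_dementia"
    spec = config.equations[key]
    mu = linear_predictor(spec, {"time_to_dx_days": time_to_dx_days,
                                 "converted": float(converted)})
    sigma = spec.dispersion
    expo = sigma if config.weibull_shape_is_sigma else 1.0 / sigma
    u = rng.uniform()
    t = float(np.exp(mu) * (-np.log(max(u, 1e-300))) ** expo)
    if arm == FLORBETABEN:
        hr = config.diagnostics.discontinuation_hr
        if config.treatment.hr_via_aft_rescaling:
            t *= (1.0 / hr) ** expo
        else:
            t *= 1.0 / hr
    return t


def apply_stopping_rules(phase: str, mmse: float, on_treatment: bool,
                         treatment_years_predementia: float, converted: bool,
                         config: ScenarioConfig) -> str | None:
    """Forced-stop check; returns the stop reason or None.

    Dementia treatment stops once MMSE falls to the floor; predementia
    treatment is capped at the configured maximum duration unless the patient
    has converted.
    """
    if not on_treatment:
        return None
    tc = config.treatment
    if phase == "dementia" and mmse <= tc.mmse_stop_floor:
        return "mmse_floor"
    if (phase == "predementia" and not converted
            and treatment_years_predementia > tc.predementia_max_years):
        return "max_duration"
    return None


def drug_from_uniform(mix: dict[str, float], u: float) -> str:
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"drug mix sums to {total!r}, not 1")
    acc = 0.0
    for drug, p in mix.items():
        acc += p
        if u < acc:
            return drug
    return list(mix)[-1]


def drug_mix_for(dx_label: str | None, phase: str, config: ScenarioConfig) -> dict[str, float]:
    tc = config.treatment
    if phase == "predementia":
        return tc.mix_predementia
    if dx_label == "AD_positive":
        return tc.mix_ad_positive
    return tc.mix_nonad


def assign_drug(dx_label: str | None, phase: str, config: ScenarioConfig,
                rng: np.random.Generator) -> str:
    """Categorical draw from the diagnosis-specific medication mix."""
    return drug_from_uniform(drug_mix_for(dx_label, phase, config), rng.uniform())


def conversion_hazard_modifier(true_cause: str, on_treatment: bool,
                               config: ScenarioConfig) -> float:
    """Multiplier on the dementia-conversion hazard.

    Treatment halves the hazard for prodromal AD only; for nonprodromal
    patients it has a cost impact but no clinical benefit.
    """
    if true_cause == "prodromalAD" and on_treatment:
        return 1.0 - config.treatment.conversion_risk_reduction
    return 1.0
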