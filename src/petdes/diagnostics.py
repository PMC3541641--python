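"""Diagnostic work-up: algorithm assignment, test accuracy, and time to
confirmation of the final diagnosis.

In the usual diagnostic care arm each patient is assigned one diagnostic
algorithm (clinical guidelines alone or clinical guidelines plus one add-on
test) from the observed usage mix; in the comparator arm every patient's
work-up includes a florbetaben amyloid-PET scan.  A confirmed AD label is
drawn against the patient's true underlying cause using the algorithm's
sensitivity/specificity, looked up at the severity band the patient has
reached by the confirmation date (disease progresses during the work-up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import PatientProfile
from .config import AlgorithmPerformance, ConfigurationError, ScenarioConfig
from .parametric_models import linear_predictor

USUAL = "usual"
FLORBETABEN = "florbetaben"


@dataclass
class DiagnosisResult:
    label: str          # "AD_positive" | "AD_negative"
    truth_class: str    # "TP" | "FP" | "TN" | "FN"
    confirmed_at: float  # simulation days

    @property
    def positive(self) -> bool:
        return self.label == "AD_positive"


def algorithm_from_uniform(arm: str, table: list[AlgorithmPerformance],
                           u: float) -> AlgorithmPerformance:
    """Pick the diagnostic algorithm from a pre-drawn uniform (common random
    numbers across arms)."""
    if arm == FLORBETABEN:
        for a in table:
            if a.algorithm == "clinical+florbetaben_PET":
                return a
        raise ConfigurationError("no florbetaben PET row in the algorithm table")
    acc = 0.0
    usual = [a for a in table if a.usual_care_share > 0]
    for a in usual:
        acc += a.usual_care_share
        if u < acc:
            return a
    return usual[-1]


def assign_algorithm(arm: str, table: list[AlgorithmPerformance],
                     rng: np.random.Generator) -> AlgorithmPerformance:
    """Sample the diagnostic algorithm for one patient.

    The florbetaben arm always uses the amyloid-PET algorithm; the usual-care
    arm samples from the observed shares.
    """
    return algorithm_from_uniform(arm, table, rng.uniform())


def diagnosis_from_uniform(is_ad_type: bool, severity: str,
                           perf: AlgorithmPerformance, u: float,
                           t: float = 0.0) -> DiagnosisResult:
    if is_ad_type:
        positive = u < perf.sens(severity)
        truth_class = "TP" if positive else "FN"
    else:
        positive = u < 1.0 - perf.spec(severity)
        truth_class = "FP" if positive else "TN"
    label = "AD_positive" if positive else "AD_negative"
    return DiagnosisResult(label=label, truth_class=truth_class, confirmed_at=t)


def draw_diagnosis(true_cause: str, severity: str, perf: AlgorithmPerformance,
                   rng: np.random.Generator, t: float = 0.0,
                   *, is_ad_type: bool | None = None) -> DiagnosisResult:
    """Draw the confirmed AD-positive/negative label for a patient.

    AD-type truth is labelled positive with probability ``sens(severity)``;
    non-AD truth with probability ``1 - spec(severity)``.
    """
    if is_ad_type is None:
        is_ad_type = true_cause in ("prodromalAD", "AD", "mixedAD")
    return diagnosis_from_uniform(is_ad_type, severity, perf, rng.uniform(), t)


def profile_covariates(profile: PatientProfile) -> dict[str, float]:
    """Baseline covariate map shared by all fitted equations."""
    cause = profile.true_cause
    dem_cause = profile.dementia_cause()
    return {
        "age": profile.age0,
        "male": float(profile.male),
        "mixed_ad": float(cause == "mixedAD"),
        "ckd": float(profile.ckd),
        "cvd": float(profile.cvd),
        "diabetes": float(profile.diabetes),
        "hypertension": float(profile.hypertension),
        "stroke": float(profile.stroke),
        "lbd": float(cause == "LBD"),
        "ftd": float(cause == "FTD"),
        "vad": float(dem_cause == "VaD"),
        "other_nonad": float(dem_cause in ("LBD", "FTD", "mixedNonAD")),
        "white": float(profile.race == "white"),
        "black": float(profile.race == "black"),
        "psymed": float(profile.psymed),
        "living_with_caregiver": float(profile.living_with_caregiver),
        "caregiver_age": profile.caregiver_age,
        "caregiver_male": float(profile.caregiver_male),
    }


def confirmation_equation(profile: PatientProfile, config: ScenarioConfig):
    """Pick the cause-matched time-to-confirmation equation."""
    eqs = config.equations
    if profile.phase0 == "predementia":
        key = "ttc_predementia"
    elif profile.true_cause in ("AD", "mixedAD"):
        key = "ttc_ad"
    elif profile.true_cause == "VaD":
        key = "ttc_vad"
    else:
        key = "ttc_other"
    try:
        return eqs[key]
    except KeyError:
        raise ConfigurationError(
            f"no time-to-confirmation equation {key!r} for cause "
            f"{profile.true_cause!r}") from None


def time_to_confirmation(profile: PatientProfile, arm: str,
                         config: ScenarioConfig, rng: np.random.Generator) -> float:
    """Days from the initial visit to diagnosis confirmation.

    A lognormal AFT draw from the cause-matched equation; the florbetaben arm
    multiplies the usual-care draw by ``1 - time_reduction`` using the same
    underlying normal deviate (common random numbers).
    """
    spec = confirmation_equation(profile, config)
    mu = linear_predictor(spec, profile_covariates(profile))
    z = rng.standard_normal()
    t = float(np.exp(mu + spec.dispersion * z))
    if arm == FLORBETABEN:
        t *= 1.0 - config.diagnostics.time_reduction
    return t


def predementia_pathway(profile: PatientProfile, arm: str, config: ScenarioConfig,
                        rng: np.random.Generator, t: float = 0.0
                        ) -> tuple[DiagnosisResult | None, bool]:
    """Diagnosis and treatment decision for a predementia patient at
    confirmation (all predementia diagnoses are correct).

    Florbetaben arm: amyloid-PET scan against the prodromal-AD truth; treat
    iff positive.  Usual arm: no scan; treat with the configured uptake
    probability irrespective of truth.
    """
    if arm == FLORBETABEN:
        perf = config.diagnostics.florbetaben()
        result = draw_diagnosis(profile.true_cause, "mild", perf, rng, t,
                                is_ad_type=profile.true_cause == "prodromalAD")
        return result, result.positive
    treated = rng.uniform() < config.treatment.uptake_usual_predementia
    return None, treated
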