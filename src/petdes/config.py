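"""Scenario configuration: every model parameter with its reference-case default.

The configuration is a tree of dataclasses.  Any leaf can be overridden from a
YAML/JSON mapping (:func:`ScenarioConfig.from_dict`) or addressed by a dotted
path such as ``"costs.institutional_per_day"`` (:func:`get_value` /
:func:`set_value`), which is how the sensitivity analyses range parameters.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

from .parametric_models import EquationSpec

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.44
DAYS_PER_WEEK = 7.0


class ConfigurationError(ValueError):
    """A scenario parameter block is internally inconsistent."""


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Baseline population mixture and samplers.

    The phase and cause mixtures reproduce the observed confirmed-diagnosis
    distribution of the source cohort: 68% dementia / 32% predementia; within
    dementia 67% AD or mixed AD, 28% vascular dementia, 5% other; within
    predementia 65% prodromal AD.  Sub-splits inside the AD-type and "other"
    groups, comorbidity prevalences and scale-score dispersions are not
    observed quantities and are exposed here so they can be ranged in
    sensitivity analyses.
    """

    p_dementia: float = 0.68
    # within dementia
    p_ad_type: float = 0.67
    p_vad: float = 0.28
    p_other: float = 0.05
    # sub-splits
    p_mixed_within_ad: float = 0.25
    p_lbd_within_other: float = 0.40
    p_ftd_within_other: float = 0.30
    p_mixed_nonad_within_other: float = 0.30
    # within predementia
    p_prodromal: float = 0.65

    mean_age_predementia: float = 78.0
    mean_age_dementia: float = 82.0
    sd_age: float = 7.0
    age_min: float = 55.0
    age_max: float = 100.0
    p_male: float = 0.30

    p_white: float = 0.85
    p_black: float = 0.10
    p_other_race: float = 0.05

    # comorbidity prevalences (model covariates; ranged in DSA)
    p_ckd: float = 0.10
    p_cvd: float = 0.15
    p_diabetes: float = 0.25
    p_hypertension: float = 0.60
    p_stroke: float = 0.10
    p_psymed: float = 0.20

    # baseline scale samplers (clamped normal)
    mmse_mean_predementia: float = 27.5
    mmse_sd_predementia: float = 1.5
    mmse_mean_dementia: float = 21.9
    mmse_sd_dementia: float = 4.0
    npi_mean_predementia: float = 2.5
    npi_sd_predementia: float = 2.0
    npi_mean_dementia: float = 16.3
    npi_sd_dementia: float = 6.0
    adl_mean_predementia: float = 10.1
    adl_sd_predementia: float = 4.0
    adl_mean_dementia: float = 29.7
    adl_sd_dementia: float = 8.0
    iadl_mean_predementia: float = 10.1
    iadl_sd_predementia: float = 4.0
    iadl_mean_dementia: float = 29.1
    iadl_sd_dementia: float = 8.0

    # caregiver attributes
    caregiver_age_offset: float = -3.0
    p_living_with_caregiver: float = 0.70

    def validate(self) -> None:
        blocks = {
            "phase": [self.p_dementia, 1.0 - self.p_dementia],
            "dementia cause": [self.p_ad_type, self.p_vad, self.p_other],
            "race": [self.p_white, self.p_black, self.p_other_race],
            "other-dementia split": [
                self.p_lbd_within_other,
                self.p_ftd_within_other,
                self.p_mixed_nonad_within_other,
            ],
        }
        for name, probs in blocks.items():
            if any(p < 0 for p in probs):
                raise ConfigurationError(f"negative probability in {name!r} block")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"proportions in {name!r} block sum to {sum(probs)!r}, not 1"
                )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

@dataclass
class AlgorithmPerformance:
    """One diagnostic algorithm: usual-care share, accuracy by severity, cost."""

    algorithm: str
    usual_care_share: float
    sens_mild: float
    spec_mild: float
    sens_modsev: float
    spec_modsev: float
    test_cost: float = 0.0

    def sens(self, severity: str) -> float:
        return self.sens_mild if severity == "mild" else self.sens_modsev

    def spec(self, severity: str) -> float:
        return self.spec_mild if severity == "mild" else self.spec_modsev


def default_algorithm_table() -> list[AlgorithmPerformance]:
    rows = [
        # (name, usual share, sens_mild, spec_mild, sens_modsev, spec_modsev, cost)
        ("clinical_only", 0.73, 0.87, 0.59, 0.77, 0.73, 0.0),
        ("clinical+MRI_MTA", 0.08, 0.82, 0.66, 0.85, 0.80, 437.0),
        ("clinical+CT_MTA", 0.19, 0.80, 0.87, 0.80, 0.87, 300.0),
        ("clinical+FDG_PET", 0.0, 0.91, 0.75, 0.91, 0.86, 1042.0),
        ("clinical+SPECT", 0.0, 0.79, 0.81, 0.68, 0.86, 596.0),
        ("clinical+CSF_Ab", 0.0, 0.72, 0.75, 0.74, 0.79, 304.0),
        ("clinical+CSF_AbTtau", 0.0, 0.86, 0.64, 0.84, 0.72, 304.0),
        ("clinical+CSF_Ttau", 0.0, 0.77, 0.73, 0.82, 0.71, 304.0),
        ("clinical+CSF_Ptau", 0.0, 0.77, 0.73, 0.82, 0.78, 304.0),
        ("clinical+florbetaben_PET", 0.0, 0.90, 0.90, 0.90, 0.90, 2300.0),
    ]
    return [AlgorithmPerformance(*r) for r in rows]


@dataclass
class DiagnosticsConfig:
    algorithms: list[AlgorithmPerformance] = field(default_factory=default_algorithm_table)
    # effects attributed to the amyloid-PET work-up
    time_reduction: float = 0.50        # fractional cut in time to confirmation
    discontinuation_hr: float = 0.50    # hazard ratio on treatment discontinuation
    # misdiagnosed (false negative) patients may be correctly re-diagnosed
    # later; exponential delay with this mean (no observed value; ranged in DSA)
    rediagnosis_mean_months: float = 24.0

    def validate(self) -> None:
        total = sum(a.usual_care_share for a in self.algorithms)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"usual-care algorithm shares sum to {total!r}, not 1"
            )
        for a in self.algorithms:
            for p in (a.sens_mild, a.spec_mild, a.sens_modsev, a.spec_modsev):
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"accuracy outside [0,1] for algorithm {a.algorithm!r}"
                    )

    def florbetaben(self) -> AlgorithmPerformance:
        for a in self.algorithms:
            if a.algorithm == "clinical+florbetaben_PET":
                return a
        raise ConfigurationError("no florbetaben PET row in the algorithm table")


# ---------------------------------------------------------------------------
# Treatment
# ---------------------------------------------------------------------------

@dataclass
class TreatmentConfig:
    # uptake at confirmation
    uptake_usual_ad_positive: float = 0.77
    uptake_usual_nonad: float = 0.67
    uptake_usual_predementia: float = 0.28
    # drug mixes by diagnosis label: donepezil / galantamine / rivastigmine / memantine
    mix_ad_positive: dict[str, float] = field(
        default_factory=lambda: {"donepezil": 0.63, "galantamine": 0.25,
                                 "rivastigmine": 0.05, "memantine": 0.07})
    mix_nonad: dict[str, float] = field(
        default_factory=lambda: {"donepezil": 0.66, "galantamine": 0.09,
                                 "rivastigmine": 0.04, "memantine": 0.21})
    mix_predementia: dict[str, float] = field(
        default_factory=lambda: {"donepezil": 0.76, "galantamine": 0.06,
                                 "rivastigmine": 0.01, "memantine": 0.17})
    # stopping rules
    mmse_stop_floor: float = 10.0
    predementia_max_years: float = 5.0
    # effect sizes
    conversion_risk_reduction: float = 0.50   # prodromal AD on treatment
    mmse_treatment_offset: float = 0.5        # points/year slower decline while treated (AD-type)
    weeks_covariate_cap: float = 52.0         # treatment benefit is maintenance-only after 1 year
    # whether the discontinuation HR is applied by AFT time-rescaling
    # (hazard-consistent) or as a plain doubling of the sampled time
    hr_via_aft_rescaling: bool = True

    def validate(self) -> None:
        for name, mix in (("AD-positive", self.mix_ad_positive),
                          ("non-AD", self.mix_nonad),
                          ("predementia", self.mix_predementia)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"drug mix for {name} sums to {sum(mix.values())!r}, not 1"
                )


# ---------------------------------------------------------------------------
# Mortality
# ---------------------------------------------------------------------------

@dataclass
class MortalityConfig:
    """Gompertz life-table mortality scaled by disease-stage hazard ratios."""

    hr_predementia: float = 1.48
    hr_ad_dementia: float = 2.84
    hr_nonad_dementia: float = 2.69
    min_age: float = 55.0


# ---------------------------------------------------------------------------
# Costs (2011 USD)
# ---------------------------------------------------------------------------

@dataclass
class CostConfig:
    # diagnostic work-up running cost, USD/year by underlying diagnosis
    workup_ad: float = 5120.0
    workup_vad: float = 5885.0
    workup_other_nonad: float = 6638.0
    workup_predementia: float = 6187.0
    # drug costs USD/day
    drug_cost_per_day: dict[str, float] = field(
        default_factory=lambda: {"donepezil": 7.79, "galantamine": 6.36,
                                 "rivastigmine": 6.11, "memantine": 7.89})
    medical_predementia: float = 5548.0
    # by severity band: mild, mildly_moderate, moderate, moderately_severe, severe
    medical_by_severity: dict[str, float] = field(
        default_factory=lambda: {"mild": 8315.0, "mildly_moderate": 12806.0,
                                 "moderate": 12806.0, "moderately_severe": 18526.0,
                                 "severe": 23227.0})
    nonmedical_by_severity: dict[str, float] = field(
        default_factory=lambda: {"mild": 154.0, "mildly_moderate": 3692.0,
                                 "moderate": 12166.0, "moderately_severe": 14209.0,
                                 "severe": 23355.0})
    # care-cost multiplier for non-AD dementia relative to AD
    fraction_vad: float = 0.84
    fraction_other_nonad: float = 0.37
    # "fraction": cost_nonAD = fraction * cost_AD (default reading);
    # "one_plus": cost_nonAD = (1 + fraction) * cost_AD
    nonad_cost_mode: str = "fraction"
    institutional_per_day: float = 373.0
    caregiver_wage_per_hour: float = 7.25
    caregiver_hours_predementia: float = 2.10
    caregiver_hours_by_severity: dict[str, float] = field(
        default_factory=lambda: {"mild": 2.10, "mildly_moderate": 3.58,
                                 "moderate": 3.58, "moderately_severe": 3.76,
                                 "severe": 5.10})

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ConfigurationError(f"negative cost input {f.name!r}")
            if isinstance(v, dict):
                for k, x in v.items():
                    if isinstance(x, (int, float)) and x < 0:
                        raise ConfigurationError(f"negative cost input {f.name}.{k}")

    def nonad_multiplier(self, true_cause: str) -> float:
        if true_cause in ("AD", "mixedAD", "prodromalAD"):
            return 1.0
        frac = self.fraction_vad if true_cause == "VaD" else self.fraction_other_nonad
        return (1.0 + frac) if self.nonad_cost_mode == "one_plus" else frac


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

@dataclass
class UtilityConfig:
    predementia_utility: float = 0.82
    nonad_adjustment: float = 0.006   # subtracted from the AD patient utility


# ---------------------------------------------------------------------------
# Progression knobs
# ---------------------------------------------------------------------------

@dataclass
class ProgressionConfig:
    review_interval_days: float = 182.625   # six-month scale re-evaluation cycle
    # piecewise-linear spline knots partitioning the previous MMSE score
    pm_knot1: float = 10.0
    pm_knot2: float = 20.0
    ftd_mmse_extra_decline: float = 4.4     # additional points/year for FTD
    conversion_mmse_step: float = 2.0       # one-time MMSE drop at conversion
    sigma_delta_mmse: float = 0.0           # per-patient random intercept SDs
    sigma_delta_npi: float = 0.0
    sigma_delta_adl: float = 0.0
    sigma_delta_iadl: float = 0.0
    adl_max: float = 54.0
    iadl_max: float = 56.0
    npi_max: float = 144.0


# ---------------------------------------------------------------------------
# Severity banding
# ---------------------------------------------------------------------------

@dataclass
class SeverityConfig:
    """MMSE cut points for the five severity bands (NICE-style banding).

    A band covers scores >= its lower bound; bands are listed from worst to
    mildest.
    """

    severe_max: float = 4.0
    moderately_severe_max: float = 9.0
    moderate_max: float = 14.0
    mildly_moderate_max: float = 20.0


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    discount_rate: float = 0.03
    max_age: float = 105.0
    wtp: float = 50000.0
    include_caregiver_costs: bool = True   # societal vs payer perspective
    # Weibull AFT dispersion read as the log-scale sigma (True) or as the
    # Weibull shape k (False)
    weibull_shape_is_sigma: bool = True
    # conversion-time parameterization: "rate" S(t)=exp(-lam t^k) or
    # "scale_power" S(t)=exp(-(lam t)^k)
    conversion_param: str = "rate"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    diagnostics: DiagnosticsConfig = field(default_factory=DiagnosticsConfig)
    treatment: TreatmentConfig = field(default_factory=TreatmentConfig)
    mortality: MortalityConfig = field(default_factory=MortalityConfig)
    costs: CostConfig = field(default_factory=CostConfig)
    utilities: UtilityConfig = field(default_factory=UtilityConfig)
    progression: ProgressionConfig = field(default_factory=ProgressionConfig)
    severity: SeverityConfig = field(default_factory=SeverityConfig)
    equations: dict[str, EquationSpec] = field(default_factory=lambda: load_default_equations())

    def validate(self) -> "ScenarioConfig":
        self.cohort.validate()
        self.diagnostics.validate()
        self.treatment.validate()
        self.costs.validate()
        return self

    # -- (de)serialization --------------------------------------------------

    @classmethod
    def from_dict(cls, overrides: dict[str, Any]) -> "ScenarioConfig":
        """Build a config from defaults, applying a (possibly nested) mapping
        of overrides.  Keys may be nested dicts or dotted paths."""
        cfg = cls()
        _apply_overrides(cfg, overrides)
        return cfg.validate()

    @classmethod
    def from_file(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                data = yaml.safe_load(fh) or {}
            else:
                data = json.load(fh)
        return cls.from_dict(data)

    def copy(self) -> "ScenarioConfig":
        return copy.deepcopy(self)


def load_default_equations() -> dict[str, EquationSpec]:
    text = resources.files("petdes.data").joinpath("equations.json").read_text()
    raw = json.loads(text)
    return {name: EquationSpec.from_dict(name, d) for name, d in raw.items()}


# ---------------------------------------------------------------------------
# Dotted-path access (used by DSA/PSA and file overrides)
# ---------------------------------------------------------------------------

def _resolve(obj: Any, parts: list[str]) -> tuple[Any, str]:
    for p in parts[:-1]:
        obj = obj[p] if isinstance(obj, dict) else getattr(obj, p)
    return obj, parts[-1]


def get_value(cfg: ScenarioConfig, path: str) -> Any:
    obj, leaf = _resolve(cfg, path.split("."))
    return obj[leaf] if isinstance(obj, dict) else getattr(obj, leaf)


def set_value(cfg: ScenarioConfig, path: str, value: Any) -> None:
    """Set a leaf in place.  The caller is expected to operate on a copy."""
    obj, leaf = _resolve(cfg, path.split("."))
    if isinstance(obj, dict):
        if leaf not in obj:
            raise KeyError(f"unknown configuration key {path!r}")
        obj[leaf] = value
    else:
        if not hasattr(obj, leaf):
            raise AttributeError(f"unknown configuration key {path!r}")
        setattr(obj, leaf, value)


def with_value(cfg: ScenarioConfig, path: str, value: Any) -> ScenarioConfig:
    out = cfg.copy()
    set_value(out, path, value)
    return out


def _apply_overrides(cfg: Any, overrides: dict[str, Any], prefix: str = "") -> None:
    for key, val in overrides.items():
        path = f"{prefix}{key}"
        if isinstance(val, dict):
            try:
                current = get_value(cfg, path)
            except (AttributeError, KeyError):
                current = None
            if dataclasses.is_dataclass(current) or isinstance(current, dict):
                _apply_overrides(cfg, val, prefix=path + ".")
                continue
        set_value(cfg, path, val)
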