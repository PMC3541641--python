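"""Disease progression: interrelated MMSE, NPI, ADL and IADL dynamics.

Cognition declines along a fitted piecewise-linear (spline) function of the
previous MMSE score; behaviour (NPI) and function (ADL/IADL) follow fitted
linear equations that share covariates with cognition.  AD and mixed-AD
patients progress on all four scales; non-AD dementia progresses on MMSE only
(with an extra fixed decline for FTD); predementia patients hold their
baseline scores until conversion.  Scores are re-evaluated on a six-month
review cycle and at every event, with annual rates pro-rated linearly inside
a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import PatientProfile, severity_band
from .config import DAYS_PER_WEEK, DAYS_PER_YEAR, ScenarioConfig
from .parametric_models import linear_predictor
from .treatment import TreatmentState


@dataclass
class DiseaseState:
    """Mutable clock-stamped state of one simulated patient."""

    t: float                     # simulation time, days
    phase: str                   # "predementia" | "dementia"
    mmse: float
    npi: float
    adl: float
    iadl: float
    severity: str
    prev_rate: float = 0.0       # last applied annual MMSE decline
    institutionalized: bool = False
    converted: bool = False
    dx_label: str | None = None
    treatment: TreatmentState = field(default_factory=TreatmentState)
    # per-patient random intercepts for the four scale equations
    delta_mmse: float = 0.0
    delta_npi: float = 0.0
    delta_adl: float = 0.0
    delta_iadl: float = 0.0

    @classmethod
    def from_profile(cls, profile: PatientProfile, config: ScenarioConfig) -> "DiseaseState":
        return cls(t=0.0, phase=profile.phase0,
                   mmse=profile.mmse0, npi=profile.npi0,
                   adl=profile.adl0, iadl=profile.iadl0,
                   severity=severity_band(profile.mmse0, config.severity))

    @property
    def on_treatment(self) -> bool:
        return self.treatment.on_treatment

    def current_age(self, profile: PatientProfile) -> float:
        return profile.age0 + self.t / DAYS_PER_YEAR


def pm_basis(prev_mmse: float, config: ScenarioConfig) -> tuple[float, float, float]:
    """Piecewise-linear partition of the previous MMSE score.

    With default knots (10, 20): PM1 = min(m, 10), PM2 = clamp(m-10, 0, 10),
    PM3 = clamp(m-20, 0, 10).
    """
    k1 = config.progression.pm_knot1
    k2 = config.progression.pm_knot2
    pm1 = min(prev_mmse, k1)
    pm2 = min(max(prev_mmse - k1, 0.0), k2 - k1)
    pm3 = min(max(prev_mmse - k2, 0.0), 30.0 - k2)
    return pm1, pm2, pm3


def _weeks(state: DiseaseState, config: ScenarioConfig) -> float:
    """Weeks of follow-up, capped: treatment benefit is maintenance-only
    after the cap (default one year)."""
    return min(state.t / DAYS_PER_WEEK, config.treatment.weeks_covariate_cap)


def _treated_flag(state: DiseaseState, profile: PatientProfile) -> float:
    """Treatment covariate: only AD-type pathology responds clinically."""
    ad_type = profile.dementia_cause() in ("AD", "mixedAD")
    return float(state.on_treatment and ad_type)


def mmse_annual_change(state: DiseaseState, profile: PatientProfile,
                       config: ScenarioConfig) -> float:
    """Annual MMSE decline (points/year; positive = decline).

    Evaluates the fitted spline equation on the previous (current) MMSE, adds
    the fixed FTD adjustment, and subtracts the configured treatment offset
    while an AD-type patient is on treatment.
    """
    pm1, pm2, pm3 = pm_basis(state.mmse, config)
    covs = {"pm1": pm1, "pm2": pm2, "pm3": pm3,
            "prev_rate": state.prev_rate, "age": profile.age0}
    rate = linear_predictor(config.equations["mmse_rate"], covs) + state.delta_mmse
    cause = profile.dementia_cause()
    if cause == "FTD":
        rate += config.progression.ftd_mmse_extra_decline
    if _treated_flag(state, profile):
        rate -= config.treatment.mmse_treatment_offset
    return rate


def _scale_covs(state: DiseaseState, profile: PatientProfile,
                config: ScenarioConfig, weeks: float) -> dict[str, float]:
    treated = _treated_flag(state, profile)
    return {
        "treated": treated,
        "weeks": weeks,
        "treated_x_weeks": treated * weeks,
        "npi_base": profile.npi0, "npi_recent": state.npi,
        "mmse_base": profile.mmse0, "mmse_recent": state.mmse,
        "adl_base": profile.adl0, "adl_recent": state.adl,
        "iadl_base": profile.iadl0, "iadl_previous": state.iadl,
        "iadl_base_x_weeks": profile.iadl0 * weeks,
        "white": float(profile.race == "white"),
        "black": float(profile.race == "black"),
        "psymed": float(profile.psymed),
        "male": float(profile.male),
        "age": profile.age0,
    }


def npi_change(state: DiseaseState, profile: PatientProfile,
               config: ScenarioConfig, weeks: float) -> float:
    covs = _scale_covs(state, profile, config, weeks)
    spec = config.equations["npi_rate"]
    # the random intercept sits inside the post-multiplied bracket
    return linear_predictor(spec, covs) + state.delta_npi * spec.post_multiplier


def adl_change(state: DiseaseState, profile: PatientProfile,
               config: ScenarioConfig, weeks: float) -> float:
    covs = _scale_covs(state, profile, config, weeks)
    return linear_predictor(config.equations["adl_rate"], covs) + state.delta_adl


def iadl_change(state: DiseaseState, profile: PatientProfile,
                config: ScenarioConfig, weeks: float) -> float:
    covs = _scale_covs(state, profile, config, weeks)
    return linear_predictor(config.equations["iadl_rate"], covs) + state.delta_iadl


def advance_state(state: DiseaseState, profile: PatientProfile, dt: float,
                  config: ScenarioConfig) -> DiseaseState:
    """Advance the clock by ``dt`` days, applying pro-rated scale changes.

    Predementia patients hold baseline scores until conversion; non-AD
    dementia progresses on MMSE only; AD-type dementia progresses on all four
    scales.  Scores are clamped to their ranges and severity re-derived.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    dt_years = dt / DAYS_PER_YEAR
    if state.phase == "dementia":
        weeks = _weeks(state, config)
        rate = mmse_annual_change(state, profile, config)
        ad_type = profile.dementia_cause() in ("AD", "mixedAD")
        if ad_type:
            d_npi = npi_change(state, profile, config, weeks)
            d_adl = adl_change(state, profile, config, weeks)
            d_iadl = iadl_change(state, profile, config, weeks)
            pc = config.progression
            state.npi = min(max(state.npi + d_npi * dt_years, 0.0), pc.npi_max)
            state.adl = min(max(state.adl + d_adl * dt_years, 0.0), pc.adl_max)
            state.iadl = min(max(state.iadl + d_iadl * dt_years, 0.0), pc.iadl_max)
        state.mmse = min(max(state.mmse - rate * dt_years, 0.0), 30.0)
        state.prev_rate = rate
        state.severity = severity_band(state.mmse, config.severity)
    state.t += dt
    return state
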