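"""Costs, utilities, and discounted accumulation over a trajectory.

Costs (2011 USD) accrue continuously at event-time resolution: diagnostic
work-up rates while the work-up is open, one-off test costs at the scan,
drug costs per day on treatment, severity-banded medical and nonmedical care
during dementia (scaled down for non-AD causes), institutional care per day
replacing community nonmedical care, and caregiver time valued at a
replacement wage while the patient lives in the community.  Patient and
caregiver utilities come from fitted regression equations and integrate into
discounted QALYs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

from .cohort import SEVERITY_BANDS, PatientProfile
from .config import DAYS_PER_MONTH, DAYS_PER_YEAR, ScenarioConfig
from .engine import Segment, Trajectory
from .parametric_models import linear_predictor


def discount_factor(t: float, rate: float) -> float:
    """Continuous-time discount multiplier ``(1 + rate) ** -t`` (t in years)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return (1.0 + rate) ** (-t)


def _discounted_years(t0: float, t1: float, rate: float) -> float:
    """``integral_{t0}^{t1} (1+rate)^{-t} dt`` with t in years."""
    if t1 <= t0:
        return 0.0
    if rate == 0.0:
        return t1 - t0
    rho = math.log1p(rate)
    return (math.exp(-rho * t0) - math.exp(-rho * t1)) / rho


def patient_utility(phase: str, mmse: float, npi: float, institutionalized: bool,
                    living_with_caregiver: bool, dementia_cause: str,
                    config: ScenarioConfig) -> float:
    """Patient utility weight: fixed for predementia, regression-based for
    dementia with a small downward adjustment for non-AD causes."""
    if phase == "predementia":
        return config.utilities.predementia_utility
    covs = {"mmse": mmse, "npi": npi,
            "institutionalized": float(institutionalized),
            "living_with_caregiver": float(living_with_caregiver)}
    u = linear_predictor(config.equations["patient_utility"], covs)
    if dementia_cause not in ("AD", "mixedAD"):
        u -= config.utilities.nonad_adjustment
    return min(max(u, 0.0), 1.0)


def caregiver_utility(profile: PatientProfile, npi: float, adl: float,
                      iadl: float, config: ScenarioConfig) -> float:
    covs = {"caregiver_age": profile.caregiver_age,
            "caregiver_male": float(profile.caregiver_male),
            "male": float(profile.male),
            "npi": npi, "adl": adl, "iadl": iadl,
            "psymed": float(profile.psymed)}
    u = linear_predictor(config.equations["caregiver_utility"], covs)
    return min(max(u, 0.0), 1.0)


@dataclass
class OutcomeSummary:
    """Per-patient (or cohort-mean) outcomes in reference-table layout."""

    n: int = 1
    survival_years: float = 0.0
    time_to_dx_months: float = 0.0
    confirmed: float = 0.0            # fraction completing the work-up
    time_predementia_years: float = 0.0
    institutionalized: float = 0.0
    time_to_institutional_years: float = 0.0   # among institutionalized
    time_in_severity: dict[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in SEVERITY_BANDS})
    caregiver_time_years: float = 0.0
    # discounted costs
    cost_workup: float = 0.0
    cost_tests: float = 0.0
    cost_drugs: float = 0.0
    cost_medical: float = 0.0
    cost_nonmedical: float = 0.0
    cost_institutional: float = 0.0
    cost_direct_medical: float = 0.0
    cost_caregiver: float = 0.0
    cost_total: float = 0.0
    # discounted QALYs
    qaly_patient: float = 0.0
    qaly_caregiver: float = 0.0
    qaly_total: float = 0.0


def _workup_rate(profile: PatientProfile, config: ScenarioConfig) -> float:
    c = config.costs
    if profile.phase0 == "predementia":
        return c.workup_predementia
    if profile.true_cause in ("AD", "mixedAD"):
        return c.workup_ad
    if profile.true_cause == "VaD":
        return c.workup_vad
    return c.workup_other_nonad


def _segment_costs(seg: Segment, profile: PatientProfile, config: ScenarioConfig,
                   out: OutcomeSummary, rate: float) -> None:
    c = config.costs
    y0, y1 = seg.t0 / DAYS_PER_YEAR, seg.t1 / DAYS_PER_YEAR
    disc = _discounted_years(y0, y1, rate)
    years = y1 - y0

    if seg.in_workup:
        out.cost_workup += _workup_rate(profile, config) * disc
    if seg.phase == "predementia":
        out.cost_medical += c.medical_predementia * disc
        out.time_predementia_years += years
        caregiver_hours = c.caregiver_hours_predementia
    else:
        mult = c.nonad_multiplier(profile.dementia_cause())
        out.cost_medical += c.medical_by_severity[seg.severity] * mult * disc
        if not seg.institutionalized:
            out.cost_nonmedical += c.nonmedical_by_severity[seg.severity] * mult * disc
        out.time_in_severity[seg.severity] += years
        caregiver_hours = c.caregiver_hours_by_severity[seg.severity]
    if seg.institutionalized:
        out.cost_institutional += c.institutional_per_day * DAYS_PER_YEAR * disc
    else:
        hours_per_year = caregiver_hours * DAYS_PER_YEAR
        out.cost_caregiver += hours_per_year * c.caregiver_wage_per_hour * disc
        out.caregiver_time_years += caregiver_hours * years * DAYS_PER_YEAR / (24.0 * DAYS_PER_YEAR)
    if seg.on_treatment and seg.drug in c.drug_cost_per_day:
        out.cost_drugs += c.drug_cost_per_day[seg.drug] * DAYS_PER_YEAR * disc


def _segment_qalys(seg: Segment, profile: PatientProfile, config: ScenarioConfig,
                   out: OutcomeSummary, rate: float) -> None:
    y0, y1 = seg.t0 / DAYS_PER_YEAR, seg.t1 / DAYS_PER_YEAR
    disc = _discounted_years(y0, y1, rate)
    u_p = patient_utility(seg.phase, seg.mmse, seg.npi, seg.institutionalized,
                          profile.living_with_caregiver, profile.dementia_cause(),
                          config)
    out.qaly_patient += u_p * disc
    if not seg.institutionalized:
        u_c = caregiver_utility(profile, seg.npi, seg.adl, seg.iadl, config)
        out.qaly_caregiver += u_c * disc


def accumulate(trajectory: Trajectory, config: ScenarioConfig) -> OutcomeSummary:
    """Integrate one trajectory into discounted costs, QALYs and clinical
    times."""
    profile = trajectory.profile
    rate = config.discount_rate
    out = OutcomeSummary()
    prev_end = 0.0
    for seg in trajectory.segments:
        if seg.t0 - prev_end > 1e-6:
            raise ValueError("trajectory has a gap in its state history")
        prev_end = seg.t1
        _segment_costs(seg, profile, config, out, rate)
        _segment_qalys(seg, profile, config, out, rate)
    for (t, _label, amount) in trajectory.point_costs:
        out.cost_tests += amount * discount_factor(t / DAYS_PER_YEAR, rate)

    out.survival_years = trajectory.survival_days / DAYS_PER_YEAR
    out.confirmed = float(trajectory.confirmed)
    if trajectory.confirmed:
        out.time_to_dx_months = trajectory.time_to_dx / DAYS_PER_MONTH
    for ev in trajectory.events:
        if ev.kind == "institutionalization":
            out.institutionalized = 1.0
            out.time_to_institutional_years = ev.t / DAYS_PER_YEAR
    out.cost_direct_medical = (out.cost_workup + out.cost_tests + out.cost_drugs
                               + out.cost_medical + out.cost_nonmedical
                               + out.cost_institutional)
    out.cost_total = out.cost_direct_medical
    if config.include_caregiver_costs:
        out.cost_total += out.cost_caregiver
    out.qaly_total = out.qaly_patient + out.qaly_caregiver
    return out


def mean_summary(summaries: list[OutcomeSummary]) -> OutcomeSummary:
    """Cohort mean of per-patient summaries.

    Time to confirmed diagnosis averages over confirmed patients only, and
    time to institutional care over institutionalized patients only, matching
    the way those rows are reported.
    """
    if not summaries:
        return OutcomeSummary(n=0)
    out = OutcomeSummary(n=len(summaries))
    n = len(summaries)
    scalar = [f.name for f in dc_fields(OutcomeSummary)
              if f.name not in ("n", "time_in_severity", "time_to_dx_months",
                                "time_to_institutional_years")]
    for name in scalar:
        setattr(out, name, sum(getattr(s, name) for s in summaries) / n)
    for band in SEVERITY_BANDS:
        out.time_in_severity[band] = sum(s.time_in_severity[band] for s in summaries) / n
    n_conf = sum(s.confirmed for s in summaries)
    if n_conf:
        out.time_to_dx_months = sum(
            s.time_to_dx_months for s in summaries if s.confirmed) / n_conf
    n_inst = sum(s.institutionalized for s in summaries)
    if n_inst:
        out.time_to_institutional_years = sum(
            s.time_to_institutional_years for s in summaries if s.institutionalized) / n_inst
    return out
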