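"""Per-patient discrete event scheduling.

Each patient is simulated event-to-event from the initial doctor visit to
death (or a maximum age): diagnostic work-up and confirmation, amyloid-PET
scan, treatment start/stop, conversion from predementia to dementia,
re-diagnosis of false negatives, institutionalization, six-monthly disease
review, and death.

Two design elements matter for comparability of the arms:

* **Common random numbers** — every stochastic quantity a patient can ever
  need is drawn up-front from its own named substream, so the usual-care and
  florbetaben arms of the same patient consume identical draws and differ
  only through parameter effects.
* **Cumulative-hazard trackers** — each pending survival event stores its
  target cumulative hazard ``-ln U``.  When a covariate change alters the
  hazard mid-course (treatment start, conversion) the pending time is
  re-solved preserving the survival fraction already consumed, so the event
  time responds to the change without introducing fresh randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .cohort import PatientProfile, generate_cohort
from .config import DAYS_PER_MONTH, DAYS_PER_YEAR, ScenarioConfig
from .diagnostics import (
    FLORBETABEN,
    USUAL,
    DiagnosisResult,
    algorithm_from_uniform,
    confirmation_equation,
    diagnosis_from_uniform,
    profile_covariates,
)
from .parametric_models import (
    gompertz_cumulative_hazard,
    linear_predictor,
    sample_weibull_aft,
    sample_weibull_rate,
)
from .progression import DiseaseState, advance_state
from .treatment import drug_from_uniform, drug_mix_for

ARMS = (USUAL, FLORBETABEN)

_PROCESSES = (
    "confirmation", "algorithm", "diagnosis", "uptake", "drug", "initiation",
    "discontinuation", "conversion", "institutionalization", "death",
    "rediagnosis", "progression",
)

_INF = math.inf
_TINY = 1e-300


def patient_streams(base_seed: int, rep: int, patient_id: int) -> dict[str, np.random.Generator]:
    """One named substream per patient per stochastic process.

    Recreating the same streams for each arm makes the arms share draws
    (common random numbers).
    """
    return {
        name: np.random.default_rng(
            np.random.SeedSequence(base_seed, spawn_key=(rep, patient_id, i)))
        for i, name in enumerate(_PROCESSES)
    }


# ---------------------------------------------------------------------------
# Hazard tracker
# ---------------------------------------------------------------------------

class HazardTracker:
    """Pending survival event driven by one uniform draw.

    Stores the target cumulative hazard ``-ln U``.  ``set_curve`` installs the
    current cumulative-hazard curve (and its inverse) in absolute simulation
    days; on every covariate change the hazard consumed under the outgoing
    curve is banked so the event time is re-solved conditionally.
    """

    def __init__(self, u: float):
        self.target = -math.log(max(u, _TINY))
        self.consumed = 0.0
        self.t_last = 0.0
        self._cum: Callable[[float], float] | None = None
        self._inv: Callable[[float], float] | None = None

    def set_curve(self, t_now: float, cum: Callable[[float], float],
                  inv: Callable[[float], float]) -> None:
        if self._cum is not None:
            self.consumed += max(0.0, self._cum(t_now) - self._cum(self.t_last))
        self.t_last = t_now
        self._cum, self._inv = cum, inv

    def time_of_event(self) -> float:
        remaining = self.target - self.consumed
        if remaining <= 0.0:
            return self.t_last
        return self._inv(self._cum(self.t_last) + remaining)


def weibull_aft_curve(mu: float, dispersion: float, *, origin: float = 0.0,
                      hr: float = 1.0, shape_is_sigma: bool = True):
    """Cumulative hazard / inverse pair for a Weibull AFT process.

    ``Lambda(t) = hr * ((t - origin)/exp(mu)) ** (1/expo)`` with ``expo`` the
    quantile exponent (sigma under the sigma-interpretation, 1/k otherwise).
    """
    a = math.exp(mu)
    expo = dispersion if shape_is_sigma else 1.0 / dispersion
    k = 1.0 / expo

    def cum(t: float) -> float:
        if t <= origin:
            return 0.0
        return hr * ((t - origin) / a) ** k

    def inv(h: float) -> float:
        return origin + a * (h / hr) ** expo

    return cum, inv


def conversion_curve(lam: float, k: float, *, hr: float = 1.0, param: str = "rate"):
    """Cumulative hazard / inverse for the conversion-to-dementia Weibull.

    Engine time is in days; the fitted scale is monthly.
    """
    def cum(t: float) -> float:
        m = max(t, 0.0) / DAYS_PER_MONTH
        if param == "rate":
            return hr * lam * m ** k
        return hr * (lam * m) ** k

    def inv(h: float) -> float:
        if param == "rate":
            m = (h / (hr * lam)) ** (1.0 / k)
        else:
            m = (h / hr) ** (1.0 / k) / lam
        return m * DAYS_PER_MONTH

    return cum, inv


def gompertz_curve(scale: float, shape: float, age0: float, *, hr: float = 1.0):
    """Cumulative hazard / inverse for age-based Gompertz mortality (days)."""
    def cum(t: float) -> float:
        return gompertz_cumulative_hazard(scale, shape, age0, max(t, 0.0) / DAYS_PER_YEAR, hr)

    def inv(h: float) -> float:
        inner = h * shape / (hr * math.exp(scale)) + math.exp(shape * age0)
        return (math.log(inner) / shape - age0) * DAYS_PER_YEAR

    return cum, inv


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class EventRecord:
    kind: str
    t: float
    payload: dict = field(default_factory=dict)


@dataclass
class Segment:
    """Piecewise-constant state over [t0, t1) for cost/QALY integration."""

    t0: float
    t1: float
    phase: str
    severity: str
    mmse: float
    npi: float
    adl: float
    iadl: float
    institutionalized: bool
    on_treatment: bool
    drug: str
    in_workup: bool


@dataclass
class Trajectory:
    profile: PatientProfile
    arm: str
    events: list[EventRecord] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    point_costs: list[tuple[float, str, float]] = field(default_factory=list)
    time_to_dx: float = _INF        # drawn confirmation time, days
    confirmed: bool = False
    scanned: bool = False
    diagnosis: DiagnosisResult | None = None
    death_time: float | None = None
    survival_days: float = 0.0

    @property
    def terminal_kind(self) -> str:
        return self.events[-1].kind if self.events else ""


# ---------------------------------------------------------------------------
# Standalone event-time operations (also used by the test oracles)
# ---------------------------------------------------------------------------

def mortality_hr(phase: str, dementia_cause: str, config: ScenarioConfig) -> float:
    if phase == "predementia":
        return config.mortality.hr_predementia
    if dementia_cause in ("AD", "mixedAD"):
        return config.mortality.hr_ad_dementia
    return config.mortality.hr_nonad_dementia


def _inst_equation_and_covs(profile: PatientProfile, phase: str,
                            time_to_dx_days: float, treated: bool,
                            config: ScenarioConfig):
    if phase == "predementia":
        spec = config.equations["inst_predementia"]
        covs = {"age": profile.age0}
    else:
        spec = config.equations["inst_dementia"]
        covs = dict(profile_covariates(profile))
        covs["time_to_dx_days"] = time_to_dx_days
        covs["treated"] = float(treated)
    return spec, covs


def time_to_institutionalization(profile: PatientProfile, phase: str,
                                 time_to_dx_days: float, treated: bool,
                                 config: ScenarioConfig,
                                 rng: np.random.Generator) -> float:
    """Unconditional Weibull AFT draw of days to institutional care."""
    spec, covs = _inst_equation_and_covs(profile, phase, time_to_dx_days, treated, config)
    mu = linear_predictor(spec, covs)
    return float(sample_weibull_aft(mu, spec.dispersion, rng,
                                    shape_is_sigma=config.weibull_shape_is_sigma))


def time_to_conversion(config: ScenarioConfig, rng: np.random.Generator,
                       hazard_modifier: float = 1.0) -> float:
    """Unconditional draw of months to dementia conversion (constant
    treatment modifier)."""
    spec = config.equations["conversion"]
    lam = spec.rate * hazard_modifier
    if config.conversion_param == "scale_power":
        # hr multiplies the hazard: Lambda = hr*(lam t)^k
        u = rng.uniform()
        h = -math.log(max(u, _TINY)) / hazard_modifier
        return h ** (1.0 / spec.dispersion) / spec.rate
    return float(sample_weibull_rate(lam, spec.dispersion, rng,
                                     param=config.conversion_param))


# ---------------------------------------------------------------------------
# Patient simulation
# ---------------------------------------------------------------------------

class _PatientSim:
    """One patient, one arm."""

    # tie-break priority when several events share a time
    _PRIORITY = ("death", "horizon", "conversion", "confirmation", "floor",
                 "discontinuation", "cap", "start", "institutionalization",
                 "rediagnosis", "review")

    def __init__(self, profile: PatientProfile, arm: str, config: ScenarioConfig,
                 streams: dict[str, np.random.Generator]):
        self.profile = profile
        self.arm = arm
        self.cfg = config
        self.traj = Trajectory(profile=profile, arm=arm)
        self.state = DiseaseState.from_profile(profile, config)
        pc = config.progression
        zs = streams["progression"].standard_normal(4)
        self.state.delta_mmse = pc.sigma_delta_mmse * zs[0]
        self.state.delta_npi = pc.sigma_delta_npi * zs[1]
        self.state.delta_adl = pc.sigma_delta_adl * zs[2]
        self.state.delta_iadl = pc.sigma_delta_iadl * zs[3]

        # --- all random material up-front (common random numbers) ---
        self.z_conf = streams["confirmation"].standard_normal()
        self.u_alg = streams["algorithm"].uniform()
        self.u_dx = streams["diagnosis"].uniform()
        self.u_uptake = streams["uptake"].uniform()
        self.u_drug = streams["drug"].uniform()
        self.z_init = streams["initiation"].standard_normal()
        self.u_disc = streams["discontinuation"].uniform()
        self.u_conv = streams["conversion"].uniform()
        self.u_inst = streams["institutionalization"].uniform()
        self.u_death = streams["death"].uniform()
        self.u_rediag = streams["rediagnosis"].uniform()
        self.u_rediag_uptake = streams["rediagnosis"].uniform()

        self.horizon = max(0.0, (config.max_age - profile.age0) * DAYS_PER_YEAR)

        # confirmation time
        spec = confirmation_equation(profile, config)
        mu = linear_predictor(spec, profile_covariates(profile))
        tdx = math.exp(mu + spec.dispersion * self.z_conf)
        if arm == FLORBETABEN:
            tdx *= 1.0 - config.diagnostics.time_reduction
        self.traj.time_to_dx = tdx

        self.algorithm = algorithm_from_uniform(arm, config.diagnostics.algorithms,
                                                self.u_alg)

        # death
        eq = config.equations["mortality_male" if profile.male else "mortality_female"]
        self._mort_scale, self._mort_shape = eq.intercept, eq.dispersion
        self.death = HazardTracker(self.u_death)
        hr = mortality_hr(profile.phase0, profile.dementia_cause(), config)
        self.death.set_curve(0.0, *gompertz_curve(self._mort_scale, self._mort_shape,
                                                  profile.age0, hr=hr))

        # conversion (predementia only)
        self.conv: HazardTracker | None = None
        if profile.phase0 == "predementia":
            self.conv = HazardTracker(self.u_conv)
            self._set_conversion_curve()

        # institutionalization
        self.inst = HazardTracker(self.u_inst)
        self._set_inst_curve()

        # pending schedules
        self.disc: HazardTracker | None = None
        self._disc_phase_at_start: str | None = None
        self._disc_origin: float = 0.0
        self.start_time: float | None = None
        self.cap_time: float | None = None
        self.rediag_time: float | None = None
        self._converted_before_confirmation = False

    # -- curve plumbing ------------------------------------------------------

    def _set_conversion_curve(self) -> None:
        from .treatment import conversion_hazard_modifier
        spec = self.cfg.equations["conversion"]
        hr = conversion_hazard_modifier(self.profile.true_cause,
                                        self.state.on_treatment, self.cfg)
        self.conv.set_curve(self.state.t, *conversion_curve(
            spec.rate, spec.dispersion, hr=hr, param=self.cfg.conversion_param))

    def _set_inst_curve(self) -> None:
        # the institutionalization benefit of medication follows the clinical
        # benefit: only AD-type treatment moves the hazard
        treated = (self.state.on_treatment
                   and self.profile.dementia_cause() in ("AD", "mixedAD"))
        spec, covs = _inst_equation_and_covs(
            self.profile, self.state.phase, self.traj.time_to_dx, treated, self.cfg)
        mu = linear_predictor(spec, covs)
        self.inst.set_curve(self.state.t, *weibull_aft_curve(
            mu, spec.dispersion, origin=0.0,
            shape_is_sigma=self.cfg.weibull_shape_is_sigma))

    def _set_death_curve(self) -> None:
        hr = mortality_hr(self.state.phase, self.profile.dementia_cause(), self.cfg)
        self.death.set_curve(self.state.t, *gompertz_curve(
            self._mort_scale, self._mort_shape, self.profile.age0, hr=hr))

    def _set_disc_curve(self) -> None:
        key = ("disc_predementia" if self._disc_phase_at_start == "predementia"
               else "disc_dementia")
        spec = self.cfg.equations[key]
        mu = linear_predictor(spec, {"time_to_dx_days": self.traj.time_to_dx,
                                     "converted": float(self.state.converted)})
        hr = 1.0
        if self.arm == FLORBETABEN:
            if self.cfg.treatment.hr_via_aft_rescaling:
                hr = self.cfg.diagnostics.discontinuation_hr
            else:
                # plain stretching of the sampled time by 1/hr
                mu = mu - math.log(self.cfg.diagnostics.discontinuation_hr)
        self.disc.set_curve(self.state.t, *weibull_aft_curve(
            mu, spec.dispersion, origin=self._disc_origin, hr=hr,
            shape_is_sigma=self.cfg.weibull_shape_is_sigma))

    # -- event helpers -------------------------------------------------------

    def _record(self, kind: str, **payload) -> None:
        self.traj.events.append(EventRecord(kind, self.state.t, payload))

    def _start_treatment(self, label: str | None) -> None:
        st = self.state
        if st.phase == "dementia" and st.mmse <= self.cfg.treatment.mmse_stop_floor:
            return  # below the treatment floor: initiation is not indicated
        if st.on_treatment or st.treatment.ever_treated:
            return  # single treatment episode
        mix = drug_mix_for(label, st.phase, self.cfg)
        drug = drug_from_uniform(mix, self.u_drug)
        st.treatment.start(st.t, drug)
        self._record("treatment_start", drug=drug)
        self._disc_phase_at_start = st.phase
        self._disc_origin = st.t
        self.disc = HazardTracker(self.u_disc)
        self._set_disc_curve()
        if st.phase == "predementia":
            self.cap_time = st.t + self.cfg.treatment.predementia_max_years * DAYS_PER_YEAR
        if self.conv is not None and not st.converted:
            self._set_conversion_curve()
        self._set_inst_curve()

    def _stop_treatment(self, reason: str, kind: str) -> None:
        st = self.state
        if not st.on_treatment:
            return
        st.treatment.stop(st.t, reason)
        self._record(kind, reason=reason)
        self.disc = None
        self.cap_time = None
        if self.conv is not None and not st.converted:
            self._set_conversion_curve()
        self._set_inst_curve()

    # -- main loop -----------------------------------------------------------

    def _candidates(self) -> dict[str, float]:
        st = self.state
        cand = {
            "death": self.death.time_of_event(),
            "horizon": self.horizon,
            "review": self._next_review(),
        }
        if not self.traj.confirmed:
            cand["confirmation"] = self.traj.time_to_dx
        if self.conv is not None and not st.converted:
            cand["conversion"] = self.conv.time_of_event()
        if not st.institutionalized:
            cand["institutionalization"] = self.inst.time_of_event()
        if self.start_time is not None and not st.treatment.ever_treated:
            cand["start"] = self.start_time
        if st.on_treatment and self.disc is not None:
            cand["discontinuation"] = self.disc.time_of_event()
        if st.on_treatment and self.cap_time is not None and not st.converted:
            cand["cap"] = self.cap_time
        if self.rediag_time is not None:
            cand["rediagnosis"] = self.rediag_time
        return cand

    def _next_review(self) -> float:
        iv = self.cfg.progression.review_interval_days
        k = math.floor(self.state.t / iv + 1e-9) + 1
        return k * iv

    def _advance_to(self, t_ev: float) -> None:
        st = self.state
        dt = t_ev - st.t
        if dt <= 0:
            return
        self.traj.segments.append(Segment(
            t0=st.t, t1=t_ev, phase=st.phase, severity=st.severity,
            mmse=st.mmse, npi=st.npi, adl=st.adl, iadl=st.iadl,
            institutionalized=st.institutionalized,
            on_treatment=st.on_treatment, drug=st.treatment.drug,
            in_workup=not self.traj.confirmed))
        advance_state(st, self.profile, dt, self.cfg)
        # MMSE treatment floor: checked at every state re-evaluation
        if (st.phase == "dementia" and st.on_treatment
                and st.mmse <= self.cfg.treatment.mmse_stop_floor):
            self._stop_treatment("mmse_floor", "mmse_floor_stop")

    def run(self) -> Trajectory:
        guard = 0
        while True:
            guard += 1
            if guard > 20000:
                raise RuntimeError("event loop failed to terminate")
            cand = self._candidates()
            t_ev = min(cand.values())
            kind = next(k for k in self._PRIORITY if cand.get(k, _INF) == t_ev)
            self._advance_to(t_ev)
            if kind == "death":
                self.traj.death_time = t_ev
                self.traj.survival_days = t_ev
                self._record("death")
                break
            if kind == "horizon":
                self.traj.survival_days = t_ev
                self._record("horizon_end")
                break
            getattr(self, f"_on_{kind}")()
        return self.traj

    # -- handlers --------------------------------------------------------

    def _on_review(self) -> None:
        pass  # scale update already applied by _advance_to

    def _on_confirmation(self) -> None:
        st = self.state
        cfg = self.cfg
        self.traj.confirmed = True
        tc = cfg.treatment
        if st.phase == "predementia" and not st.converted:
            # all predementia diagnoses are correct
            if self.arm == FLORBETABEN:
                perf = cfg.diagnostics.florbetaben()
                result = diagnosis_from_uniform(
                    self.profile.true_cause == "prodromalAD", "mild", perf,
                    self.u_dx, st.t)
                self.traj.scanned = True
                self.traj.diagnosis = result
                st.dx_label = result.label
                self.traj.point_costs.append((st.t, "test", perf.test_cost))
                self._record("scan", label=result.label, truth_class=result.truth_class)
                self._record("confirmation", phase="predementia")
                if result.positive:
                    self._start_treatment(result.label)
                elif result.truth_class == "FN":
                    self._schedule_rediagnosis()
            else:
                self._record("confirmation", phase="predementia")
                if self.u_uptake < tc.uptake_usual_predementia:
                    self._start_treatment(None)
                else:
                    self._schedule_delayed_initiation("predementia")
            return
        # dementia-phase confirmation
        if self._converted_before_confirmation:
            # converted during work-up: no scan; diagnosis taken as correct
            is_ad = self.profile.dementia_cause() in ("AD", "mixedAD")
            label = "AD_positive" if is_ad else "AD_negative"
            result = DiagnosisResult(label=label,
                                     truth_class="TP" if is_ad else "TN",
                                     confirmed_at=st.t)
            perf = None
        else:
            perf = (cfg.diagnostics.florbetaben() if self.arm == FLORBETABEN
                    else self.algorithm)
            sev = "mild" if st.severity == "mild" else "modsev"
            result = diagnosis_from_uniform(self.profile.is_ad_type, sev, perf,
                                            self.u_dx, st.t)
            if perf.test_cost > 0:
                self.traj.point_costs.append((st.t, "test", perf.test_cost))
            if self.arm == FLORBETABEN:
                self.traj.scanned = True
                self._record("scan", label=result.label,
                             truth_class=result.truth_class)
        self.traj.diagnosis = result
        st.dx_label = result.label
        self._record("confirmation", phase="dementia", label=result.label,
                     truth_class=result.truth_class)
        # uptake
        if self.arm == FLORBETABEN and perf is not None:
            treat_now = result.positive
            can_delay = False
        else:
            p = (tc.uptake_usual_ad_positive if result.positive
                 else tc.uptake_usual_nonad)
            treat_now = self.u_uptake < p
            can_delay = True
        if treat_now:
            self._start_treatment(result.label)
        elif can_delay:
            self._schedule_delayed_initiation("dementia")
        if result.truth_class == "FN":
            self._schedule_rediagnosis()

    def _schedule_delayed_initiation(self, phase: str) -> None:
        key = "tti_predementia" if phase == "predementia" else "tti_dementia"
        spec = self.cfg.equations[key]
        covs = dict(profile_covariates(self.profile))
        covs["time_to_dx_days"] = self.traj.time_to_dx
        mu = linear_predictor(spec, covs)
        delay = math.exp(mu + spec.dispersion * self.z_init)
        self.start_time = self.state.t + delay

    def _schedule_rediagnosis(self) -> None:
        mean_days = self.cfg.diagnostics.rediagnosis_mean_months * DAYS_PER_MONTH
        self.rediag_time = self.state.t - math.log(max(self.u_rediag, _TINY)) * mean_days

    def _on_start(self) -> None:
        self.start_time = None
        self._start_treatment(self.state.dx_label)

    def _on_discontinuation(self) -> None:
        self._stop_treatment("discontinued", "treatment_stop")

    def _on_cap(self) -> None:
        self._stop_treatment("max_duration", "predementia_cap_stop")

    def _on_conversion(self) -> None:
        st = self.state
        st.converted = True
        st.phase = "dementia"
        st.mmse = max(0.0, st.mmse - self.cfg.progression.conversion_mmse_step)
        from .cohort import severity_band
        st.severity = severity_band(st.mmse, self.cfg.severity)
        st.prev_rate = 0.0
        self._record("conversion", cause=self.profile.dementia_cause())
        self._set_death_curve()
        self._set_inst_curve()
        if st.on_treatment and self.disc is not None:
            self._set_disc_curve()   # the converted covariate enters the clock
        self.cap_time = None
        if not self.traj.confirmed:
            self._converted_before_confirmation = True

    def _on_institutionalization(self) -> None:
        self.state.institutionalized = True
        self._record("institutionalization")

    def _on_rediagnosis(self) -> None:
        st = self.state
        self.rediag_time = None
        if self.traj.diagnosis is None or self.traj.diagnosis.truth_class != "FN":
            return
        st.dx_label = "AD_positive"
        self._record("rediagnosis", label="AD_positive")
        if not st.treatment.ever_treated and not st.on_treatment:
            if self.u_rediag_uptake < self.cfg.treatment.uptake_usual_ad_positive:
                self._start_treatment("AD_positive")

    def _on_floor(self) -> None:  # handled inside _advance_to
        pass


def simulate_patient(profile: PatientProfile, arm: str, config: ScenarioConfig,
                     streams: dict[str, np.random.Generator]) -> Trajectory:
    """Simulate one patient in one arm; see the module docstring."""
    return _PatientSim(profile, arm, config, streams).run()


def run_cohort(config: ScenarioConfig, n: int, reps: int, base_seed: int
               ) -> list[tuple[PatientProfile, Trajectory, Trajectory]]:
    """Simulate ``reps`` fresh cohorts of ``n`` patients in both arms.

    Returns one (profile, usual-care trajectory, florbetaben trajectory)
    triple per patient; deterministic for a fixed ``base_seed``.
    """
    if n < 1 or reps < 1:
        raise ValueError("n and reps must be >= 1")
    out = []
    for rep in range(reps):
        cohort = generate_cohort(config, n, seed=_rep_seed(base_seed, rep))
        for profile in cohort:
            tu = simulate_patient(profile, USUAL, config,
                                  patient_streams(base_seed, rep, profile.id))
            tf = simulate_patient(profile, FLORBETABEN, config,
                                  patient_streams(base_seed, rep, profile.id))
            out.append((profile, tu, tf))
    return out


def _rep_seed(base_seed: int, rep: int) -> int:
    return int(np.random.SeedSequence(base_seed, spawn_key=(rep,)).generate_state(1)[0] % (2**31))
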