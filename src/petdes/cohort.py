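"""Synthetic baseline cohort generation.

Patients enter the simulation at their first doctor visit in either the
predementia or dementia phase, carrying an underlying (true) cause of their
cognitive decline, demographics, comorbidity flags, caregiver attributes, and
baseline MMSE/NPI/ADL/IADL scores.  The mixtures reproduce the confirmed
diagnosis distribution of the source population; see
:class:`petdes.config.CohortConfig` for the dials.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .config import CohortConfig, ScenarioConfig, SeverityConfig

AD_TYPE_CAUSES = frozenset({"prodromalAD", "AD", "mixedAD"})
PREDEMENTIA_CAUSES = frozenset({"prodromalAD", "nonprodromalAD"})
DEMENTIA_CAUSES = frozenset({"AD", "mixedAD", "VaD", "LBD", "FTD", "mixedNonAD"})

SEVERITY_BANDS = ("mild", "mildly_moderate", "moderate", "moderately_severe", "severe")


@dataclass(frozen=True)
class PatientProfile:
    """Immutable baseline truth for one simulated patient."""

    id: int
    phase0: str                      # "predementia" | "dementia"
    true_cause: str
    # for predementia patients: the dementia type they would convert into
    latent_dementia_cause: str
    age0: float
    male: bool
    race: str                        # "white" | "black" | "other"
    ckd: bool
    cvd: bool
    diabetes: bool
    hypertension: bool
    stroke: bool
    psymed: bool
    living_with_caregiver: bool
    caregiver_age: float
    caregiver_male: bool
    mmse0: float
    npi0: float
    adl0: float
    iadl0: float

    def __post_init__(self) -> None:
        if self.phase0 == "predementia" and self.true_cause not in PREDEMENTIA_CAUSES:
            raise ValueError(f"predementia patient with cause {self.true_cause!r}")
        if self.phase0 == "dementia" and self.true_cause not in DEMENTIA_CAUSES:
            raise ValueError(f"dementia patient with cause {self.true_cause!r}")
        if not 0.0 <= self.mmse0 <= 30.0:
            raise ValueError(f"baseline MMSE {self.mmse0} outside [0, 30]")
        if not 0.0 <= self.npi0 <= 144.0:
            raise ValueError(f"baseline NPI {self.npi0} outside [0, 144]")

    @property
    def is_ad_type(self) -> bool:
        """True when the underlying pathology responds to dementia treatment."""
        return self.true_cause in AD_TYPE_CAUSES

    def dementia_cause(self) -> str:
        """The dementia-type cause: itself for dementia patients, the latent
        type for predementia patients (used after conversion)."""
        return self.true_cause if self.phase0 == "dementia" else self.latent_dementia_cause


def severity_band(mmse: float, severity: SeverityConfig | None = None) -> str:
    """Map an MMSE score to one of five severity bands (total on [0, 30])."""
    if not 0.0 <= mmse <= 30.0:
        raise ValueError(f"MMSE {mmse} outside [0, 30]")
    sev = severity or SeverityConfig()
    if mmse <= sev.severe_max:
        return "severe"
    if mmse <= sev.moderately_severe_max:
        return "moderately_severe"
    if mmse <= sev.moderate_max:
        return "moderate"
    if mmse <= sev.mildly_moderate_max:
        return "mildly_moderate"
    return "mild"


def _clamped_normal(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _draw_cause(cc: CohortConfig, phase: str, rng: np.random.Generator) -> str:
    if phase == "predementia":
        return "prodromalAD" if rng.uniform() < cc.p_prodromal else "nonprodromalAD"
    u = rng.uniform()
    if u < cc.p_ad_type:
        return "mixedAD" if rng.uniform() < cc.p_mixed_within_ad else "AD"
    if u < cc.p_ad_type + cc.p_vad:
        return "VaD"
    return _draw_other_type(cc, rng)


def _draw_other_type(cc: CohortConfig, rng: np.random.Generator) -> str:
    u = rng.uniform()
    if u < cc.p_lbd_within_other:
        return "LBD"
    if u < cc.p_lbd_within_other + cc.p_ftd_within_other:
        return "FTD"
    return "mixedNonAD"


def _draw_latent_dementia_cause(cc: CohortConfig, true_cause: str,
                                rng: np.random.Generator) -> str:
    """Dementia type a predementia patient would convert into.

    Prodromal AD converts to AD-type; nonprodromal patients receive a non-AD
    type drawn from the dementia-phase non-AD mix.
    """
    if true_cause == "prodromalAD":
        return "mixedAD" if rng.uniform() < cc.p_mixed_within_ad else "AD"
    p_vad_given_nonad = cc.p_vad / (cc.p_vad + cc.p_other)
    if rng.uniform() < p_vad_given_nonad:
        return "VaD"
    return _draw_other_type(cc, rng)


def assign_baseline_scales(profile: PatientProfile, config: ScenarioConfig,
                           rng: np.random.Generator) -> PatientProfile:
    """Draw baseline MMSE/NPI/ADL/IADL for a profile with phase and cause set.

    Samplers are normals clamped to the scale ranges; phase-specific means
    and SDs come from the cohort config.
    """
    cc = config.cohort
    pc = config.progression
    pre = profile.phase0 == "predementia"
    mmse = _clamped_normal(
        rng,
        cc.mmse_mean_predementia if pre else cc.mmse_mean_dementia,
        cc.mmse_sd_predementia if pre else cc.mmse_sd_dementia, 0.0, 30.0)
    npi = _clamped_normal(
        rng,
        cc.npi_mean_predementia if pre else cc.npi_mean_dementia,
        cc.npi_sd_predementia if pre else cc.npi_sd_dementia, 0.0, pc.npi_max)
    adl = _clamped_normal(
        rng,
        cc.adl_mean_predementia if pre else cc.adl_mean_dementia,
        cc.adl_sd_predementia if pre else cc.adl_sd_dementia, 0.0, pc.adl_max)
    iadl = _clamped_normal(
        rng,
        cc.iadl_mean_predementia if pre else cc.iadl_mean_dementia,
        cc.iadl_sd_predementia if pre else cc.iadl_sd_dementia, 0.0, pc.iadl_max)
    return PatientProfile(**{**_as_dict(profile),
                             "mmse0": mmse, "npi0": npi, "adl0": adl, "iadl0": iadl})


def _as_dict(profile: PatientProfile) -> dict:
    return {f.name: getattr(profile, f.name) for f in dc_fields(PatientProfile)}


def generate_cohort(config: ScenarioConfig, n: int, seed: int) -> list[PatientProfile]:
    """Generate ``n`` baseline patients; deterministic for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config.validate()
    cc = config.cohort
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xC0,)))
    out: list[PatientProfile] = []
    for i in range(n):
        phase = "dementia" if rng.uniform() < cc.p_dementia else "predementia"
        cause = _draw_cause(cc, phase, rng)
        latent = (cause if phase == "dementia"
                  else _draw_latent_dementia_cause(cc, cause, rng))
        age_mean = cc.mean_age_dementia if phase == "dementia" else cc.mean_age_predementia
        age = _clamped_normal(rng, age_mean, cc.sd_age, cc.age_min, cc.age_max)
        male = rng.uniform() < cc.p_male
        u = rng.uniform()
        race = "white" if u < cc.p_white else ("black" if u < cc.p_white + cc.p_black else "other")
        prof = PatientProfile(
            id=i, phase0=phase, true_cause=cause, latent_dementia_cause=latent,
            age0=age, male=male, race=race,
            ckd=rng.uniform() < cc.p_ckd,
            cvd=rng.uniform() < cc.p_cvd,
            diabetes=rng.uniform() < cc.p_diabetes,
            hypertension=rng.uniform() < cc.p_hypertension,
            stroke=rng.uniform() < cc.p_stroke,
            psymed=rng.uniform() < cc.p_psymed,
            living_with_caregiver=rng.uniform() < cc.p_living_with_caregiver,
            caregiver_age=max(18.0, age + cc.caregiver_age_offset),
            caregiver_male=not male,
            mmse0=30.0, npi0=0.0, adl0=0.0, iadl0=0.0)
        out.append(assign_baseline_scales(prof, config, rng))
    return out


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_COLUMNS = [f.name for f in dc_fields(PatientProfile)]


def cohort_to_csv(cohort: list[PatientProfile], path: str, seed: int | None = None) -> None:
    """One row per patient, documented column order; seed kept in a header
    comment so a dump can be audited against its generator call."""
    df = pd.DataFrame([_as_dict(p) for p in cohort], columns=_COLUMNS)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def cohort_from_csv(path: str) -> list[PatientProfile]:
    with open(path) as fh:
        text = "".join(line for line in fh if not line.startswith("#"))
    df = pd.read_csv(io.StringIO(text), float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        d = {c: row[c] for c in _COLUMNS}
        for flag in ("male", "ckd", "cvd", "diabetes", "hypertension", "stroke",
                     "psymed", "living_with_caregiver", "caregiver_male"):
            d[flag] = bool(d[flag])
        d["id"] = int(d["id"])
        out.append(PatientProfile(**d))
    return out
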