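"""Reference-case runner, sensitivity analyses, and cost-effectiveness
summarization.

The reference case simulates replicated cohorts through both arms under
common random numbers, reports the predementia and dementia sub-cohorts
separately, and classifies the incremental result (dominant / dominated /
ICER against a willingness-to-pay threshold).  One-way deterministic
sensitivity analysis re-runs the reference case at the low and high bound of
each parameter (tornado table); probabilistic sensitivity analysis samples
parameter sets from assigned distributions and maps the cloud of incremental
outcomes on the cost-effectiveness plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SEVERITY_BANDS
from .config import ScenarioConfig, get_value, with_value
from .diagnostics import FLORBETABEN, USUAL
from .economics import OutcomeSummary, accumulate, mean_summary
from .engine import Trajectory, run_cohort


# ---------------------------------------------------------------------------
# CE classification
# ---------------------------------------------------------------------------

@dataclass
class CEResult:
    net_cost: float
    net_qaly: float
    classification: str          # "dominant" | "dominated" | "ICER"
    icer: float | None
    quadrant: str                # NE | SE | SW | NW
    cost_effective: bool


def classify(net_cost: float, net_qaly: float, wtp: float) -> CEResult:
    """Locate an incremental result on the cost-effectiveness plane.

    Dominant: gains QALYs and saves money; dominated: the reverse; otherwise
    the ICER is reported.  Cost-effectiveness uses the net-monetary-benefit
    rule ``wtp * dQ - dC > 0``, which also covers the south-west quadrant
    (QALYs lost but savings above the threshold value of the loss).
    """
    if net_qaly > 0:
        quadrant = "NE" if net_cost > 0 else "SE"
    elif net_qaly < 0:
        quadrant = "NW" if net_cost > 0 else "SW"
    else:
        quadrant = "NE" if net_cost > 0 else "SE"
    if net_qaly > 0 and net_cost < 0:
        return CEResult(net_cost, net_qaly, "dominant", None, quadrant, True)
    if net_qaly < 0 and net_cost > 0:
        return CEResult(net_cost, net_qaly, "dominated", None, quadrant, False)
    icer = net_cost / net_qaly if net_qaly != 0 else None
    nmb = wtp * net_qaly - net_cost
    # at the threshold (ICER == WTP) the option counts as acceptable; QALY
    # losses must be strictly over-compensated by savings
    ce = nmb >= 0 if net_qaly > 0 else nmb > 0
    return CEResult(net_cost, net_qaly, "ICER", icer, quadrant, ce)


# ---------------------------------------------------------------------------
# Reference case
# ---------------------------------------------------------------------------

@dataclass
class CohortOutcome:
    usual: OutcomeSummary
    florbetaben: OutcomeSummary
    ce: CEResult

    @property
    def net_cost(self) -> float:
        return self.ce.net_cost

    @property
    def net_qaly(self) -> float:
        return self.ce.net_qaly


@dataclass
class RunResult:
    predementia: CohortOutcome
    dementia: CohortOutcome
    triples: list | None = None   # (profile, usual traj, florbetaben traj)


def _summarize_arm(triples, config: ScenarioConfig, phase: str, arm_index: int
                   ) -> OutcomeSummary:
    summaries = [accumulate(t[arm_index], config)
                 for t in triples if t[0].phase0 == phase]
    return mean_summary(summaries)


def reference_case(config: ScenarioConfig | None = None, n: int = 1000,
                   reps: int = 10, seed: int = 1, keep_triples: bool = False
                   ) -> RunResult:
    """Run both arms over ``reps`` cohorts of ``n`` patients and aggregate."""
    config = (config or ScenarioConfig()).validate()
    triples = run_cohort(config, n, reps, seed)
    cohorts = {}
    for phase in ("predementia", "dementia"):
        u = _summarize_arm(triples, config, phase, 1)
        f = _summarize_arm(triples, config, phase, 2)
        ce = classify(f.cost_total - u.cost_total, f.qaly_total - u.qaly_total,
                      config.wtp)
        cohorts[phase] = CohortOutcome(usual=u, florbetaben=f, ce=ce)
    return RunResult(predementia=cohorts["predementia"],
                     dementia=cohorts["dementia"],
                     triples=triples if keep_triples else None)


_ROWS = [
    ("Survival, years", "survival_years"),
    ("Time to confirmed diagnosis, months", "time_to_dx_months"),
    ("Time in predementia, years", "time_predementia_years"),
    ("Time to institutional care, years", "time_to_institutional_years"),
    ("Caregiver time, years", "caregiver_time_years"),
    ("Total direct medical care, $", "cost_direct_medical"),
    ("Caregiver time, $", "cost_caregiver"),
    ("Total cost, $", "cost_total"),
    ("Patient QALYs", "qaly_patient"),
    ("Caregiver QALYs", "qaly_caregiver"),
    ("Total QALYs", "qaly_total"),
]


def result_table(result: RunResult) -> pd.DataFrame:
    """Reference-case outcomes in the standard usual / florbetaben / net
    layout, one block per cohort."""
    records = []
    for phase, co in (("predementia", result.predementia),
                      ("dementia", result.dementia)):
        for label, attr in _ROWS:
            u, f = getattr(co.usual, attr), getattr(co.florbetaben, attr)
            records.append({"cohort": phase, "outcome": label,
                            "usual_care": u, "florbetaben": f, "net": f - u})
        for band in SEVERITY_BANDS:
            u = co.usual.time_in_severity[band]
            f = co.florbetaben.time_in_severity[band]
            records.append({"cohort": phase,
                            "outcome": f"Time in severity ({band}), years",
                            "usual_care": u, "florbetaben": f, "net": f - u})
        records.append({"cohort": phase, "outcome": "ICER",
                        "usual_care": "", "florbetaben": "",
                        "net": co.ce.classification if co.ce.icer is None
                        else f"{co.ce.icer:.0f}"})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Diagnostic bookkeeping (shared by reports and the acceptance checks)
# ---------------------------------------------------------------------------

def scan_confusion(triples, phase: str, arm_index: int,
                   require_scan: bool = False) -> dict[str, float]:
    """Confusion-matrix shares (percent) among patients of ``phase`` whose
    work-up completed with a diagnosis, for the given arm.

    With ``require_scan`` the denominator is restricted to patients who
    actually received the amyloid-PET scan (patients converting or dying
    during the work-up never do).
    """
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    total = 0
    for t in triples:
        if t[0].phase0 != phase:
            continue
        traj: Trajectory = t[arm_index]
        if traj.diagnosis is None or (require_scan and not traj.scanned):
            continue
        counts[traj.diagnosis.truth_class] += 1
        total += 1
    if total == 0:
        return {k: float("nan") for k in ("TP", "FP", "TN", "FN", "positive")}
    out = {k: 100.0 * v / total for k, v in counts.items()}
    out["positive"] = out["TP"] + out["FP"]
    out["n"] = total
    return out


def workup_completion(triples, phase: str, arm_index: int) -> float:
    """Percent of patients surviving (and not converting out of) the work-up
    to a confirmed diagnosis."""
    flags = [t[arm_index].confirmed for t in triples if t[0].phase0 == phase]
    return 100.0 * float(np.mean(flags)) if flags else float("nan")


def scanned_fraction(triples, phase: str, arm_index: int = 2) -> float:
    flags = [t[arm_index].scanned for t in triples if t[0].phase0 == phase]
    return 100.0 * float(np.mean(flags)) if flags else float("nan")


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

def default_dsa_ranges(config: ScenarioConfig) -> dict[str, tuple[float, float]]:
    """Default one-way ranges: the named scenario levers plus ±20% on the
    main unobserved inputs."""
    ranges: dict[str, tuple[float, float]] = {
        "diagnostics.time_reduction": (0.0, 0.75),
        "diagnostics.discontinuation_hr": (0.5, 1.0),
        "treatment.conversion_risk_reduction": (0.25, 0.50),
        "treatment.uptake_usual_predementia": (0.28, 1.0),
    }
    pm20 = [
        "diagnostics.rediagnosis_mean_months",
        "treatment.uptake_usual_ad_positive",
        "treatment.uptake_usual_nonad",
        "treatment.mmse_treatment_offset",
        "costs.institutional_per_day",
        "costs.caregiver_wage_per_hour",
        "costs.medical_predementia",
        "cohort.p_ckd",
        "cohort.p_hypertension",
        "cohort.mmse_sd_dementia",
        "progression.conversion_mmse_step",
        "utilities.predementia_utility",
    ]
    for path in pm20:
        v = get_value(config, path)
        ranges[path] = (0.8 * v, min(1.2 * v, 1.0) if "utilit" in path or "uptake" in path
                        else 1.2 * v)
    return ranges


def one_way_dsa(config: ScenarioConfig, param_ranges: dict[str, tuple[float, float]]
                | None = None, n: int = 200, reps: int = 2, seed: int = 1,
                top: int = 15) -> dict[str, pd.DataFrame]:
    """Tornado analysis: net total cost at each parameter's low and high
    bound (common random numbers across all runs), sorted by swing."""
    config = (config or ScenarioConfig()).validate()
    param_ranges = param_ranges if param_ranges is not None else default_dsa_ranges(config)
    if len(set(param_ranges)) != len(param_ranges):
        raise ValueError("overlapping parameter names")
    base = reference_case(config, n=n, reps=reps, seed=seed)
    base_net = {"predementia": base.predementia.net_cost,
                "dementia": base.dementia.net_cost}
    rows: dict[str, list[dict]] = {"predementia": [], "dementia": []}
    for path, (low, high) in param_ranges.items():
        nets = {}
        for bound, value in (("low", low), ("high", high)):
            if low == high and bound == "high":
                nets["high"] = nets["low"]
                continue
            res = reference_case(with_value(config, path, value),
                                 n=n, reps=reps, seed=seed)
            nets[bound] = {"predementia": res.predementia.net_cost,
                           "dementia": res.dementia.net_cost}
        for phase in rows:
            lo, hi = nets["low"][phase], nets["high"][phase]
            rows[phase].append({
                "parameter": path, "low": low, "high": high,
                "net_cost_low": lo, "net_cost_high": hi,
                "net_cost_base": base_net[phase],
                "swing": abs(hi - lo)})
    out = {}
    for phase, recs in rows.items():
        df = pd.DataFrame.from_records(recs).sort_values(
            "swing", ascending=False, kind="mergesort").reset_index(drop=True)
        out[phase] = df.head(top) if top else df
    return out


def sweep_2d(config: ScenarioConfig, path_a: str, values_a, path_b: str, values_b,
             n: int = 200, reps: int = 2, seed: int = 1) -> pd.DataFrame:
    """Generic two-parameter scenario grid (net cost and net QALYs)."""
    records = []
    for va in values_a:
        for vb in values_b:
            cfg = with_value(with_value(config, path_a, va), path_b, vb)
            res = reference_case(cfg, n=n, reps=reps, seed=seed)
            for phase, co in (("predementia", res.predementia),
                              ("dementia", res.dementia)):
                records.append({path_a: va, path_b: vb, "cohort": phase,
                                "net_cost": co.net_cost, "net_qaly": co.net_qaly,
                                "classification": co.ce.classification})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def _draw_param(dist: tuple, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "point":
        return float(dist[1])
    mean, se = float(dist[1]), float(dist[2])
    if se == 0:
        return mean
    if kind == "beta":
        if not 0 < mean < 1:
            raise ValueError(f"beta mean {mean} outside (0,1)")
        var = min(se * se, 0.999 * mean * (1 - mean))
        nu = mean * (1 - mean) / var - 1.0
        return float(rng.beta(mean * nu, (1 - mean) * nu))
    if kind == "gamma":
        shape = (mean / se) ** 2
        return float(rng.gamma(shape, se * se / mean))
    if kind == "normal":
        return float(rng.normal(mean, se))
    raise ValueError(f"unknown distribution kind {kind!r}")


def default_psa_distributions(config: ScenarioConfig) -> dict[str, tuple]:
    """Second-order distributions for the unobserved inputs: Beta for
    probabilities and utilities (SE 10% of mean), Gamma for costs (SE 20%),
    Normal for effect multipliers (SE 10%)."""
    dists: dict[str, tuple] = {}
    for path in ("treatment.uptake_usual_ad_positive", "treatment.uptake_usual_nonad",
                 "treatment.uptake_usual_predementia", "utilities.predementia_utility",
                 "cohort.p_prodromal"):
        m = get_value(config, path)
        dists[path] = ("beta", m, 0.10 * m)
    for path in ("costs.institutional_per_day", "costs.medical_predementia",
                 "costs.caregiver_wage_per_hour", "costs.workup_ad",
                 "costs.workup_predementia"):
        m = get_value(config, path)
        dists[path] = ("gamma", m, 0.20 * m)
    for path in ("diagnostics.time_reduction", "diagnostics.discontinuation_hr",
                 "treatment.conversion_risk_reduction"):
        m = get_value(config, path)
        dists[path] = ("normal", m, 0.10 * m)
    return dists


def psa(config: ScenarioConfig | None = None, distributions: dict[str, tuple]
        | None = None, reps: int = 1000, n: int = 100, seed: int = 1
        ) -> pd.DataFrame:
    """Probabilistic sensitivity analysis.

    Each replication draws one parameter set, re-runs a cohort through both
    arms, and records the incremental cost and QALYs per cohort.  Use
    :func:`ceac` on the output for the acceptability summary.
    """
    config = (config or ScenarioConfig()).validate()
    if distributions is None:
        distributions = default_psa_distributions(config)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x5A,)))
    records = []
    for rep in range(reps):
        cfg = config.copy()
        for path, dist in distributions.items():
            value = _draw_param(dist, rng)
            if path.startswith(("treatment.uptake", "utilities.", "cohort.p_",
                                "diagnostics.time_reduction",
                                "treatment.conversion_risk_reduction")):
                value = min(max(value, 0.0), 1.0)
            from .config import set_value
            set_value(cfg, path, value)
        res = reference_case(cfg, n=n, reps=1, seed=seed + 1 + rep)
        for phase, co in (("predementia", res.predementia),
                          ("dementia", res.dementia)):
            records.append({"rep": rep, "cohort": phase,
                            "net_cost": co.net_cost, "net_qaly": co.net_qaly,
                            "quadrant": co.ce.quadrant})
    return pd.DataFrame.from_records(records)


def ceac(psa_points: pd.DataFrame, wtp: float, cohort: str | None = None) -> float:
    """Fraction of PSA replicates cost-effective at the given threshold."""
    df = psa_points if cohort is None else psa_points[psa_points["cohort"] == cohort]
    if np.isinf(wtp):
        return float((df["net_qaly"] > 0).mean())
    nmb = wtp * df["net_qaly"] - df["net_cost"]
    return float((nmb > 0).mean())
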