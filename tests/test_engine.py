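"""Event scheduling: ordering, common random numbers, and hazard re-solving."""

import math

import numpy as np
import pytest

from petdes.config import DAYS_PER_YEAR, ScenarioConfig
from petdes.diagnostics import FLORBETABEN, USUAL
from petdes.economics import accumulate
from petdes.engine import (
    HazardTracker,
    gompertz_curve,
    mortality_hr,
    patient_streams,
    run_cohort,
    simulate_patient,
    time_to_conversion,
    time_to_institutionalization,
    weibull_aft_curve,
)
from petdes.parametric_models import gompertz_cumulative_hazard

from conftest import make_profile

TERMINAL = {"death", "horizon_end"}


def _simulate(profile, arm, cfg, seed=0, pid=None):
    return simulate_patient(profile, arm, cfg,
                            patient_streams(seed, 0, pid if pid is not None else profile.id))


class TestHazardTracker:
    def test_constant_curve_reproduces_aft_draw(self):
        u = 0.37
        tr = HazardTracker(u)
        tr.set_curve(0.0, *weibull_aft_curve(7.0, 0.9))
        expected = math.exp(7.0) * (-math.log(u)) ** 0.9
        assert tr.time_of_event() == pytest.approx(expected, rel=1e-12)

    def test_hazard_change_preserves_consumed_fraction(self):
        """Re-solving at a covariate change leaves the event time continuous
        in the change and consistent with the piecewise hazard."""
        u = 0.2
        tr = HazardTracker(u)
        cum1, inv1 = weibull_aft_curve(6.0, 0.8)
        tr.set_curve(0.0, cum1, inv1)
        t_plain = tr.time_of_event()
        # install the same curve midway: nothing should change
        tr.set_curve(t_plain / 2, cum1, inv1)
        assert tr.time_of_event() == pytest.approx(t_plain, rel=1e-9)
        # now halve the hazard for the remainder: remaining hazard doubles in time
        t_switch = tr.t_last
        cum2, inv2 = weibull_aft_curve(6.0, 0.8, hr=0.5)
        tr.set_curve(t_switch, cum2, inv2)
        t_new = tr.time_of_event()
        assert t_new > t_plain
        consumed = cum1(t_switch)
        assert consumed + (cum2(t_new) - cum2(t_switch)) == pytest.approx(
            -math.log(u), rel=1e-9)


class TestEventOrdering:
    def test_no_event_after_terminal_and_times_sorted(self, cfg):
        triples = run_cohort(cfg, 60, 1, base_seed=101)
        for _, tu, tf in triples:
            for traj in (tu, tf):
                times = [e.t for e in traj.events]
                assert times == sorted(times)
                assert all(t >= 0 for t in times)
                assert traj.events[-1].kind in TERMINAL
                assert not any(e.kind in TERMINAL for e in traj.events[:-1])

    def test_segments_cover_lifetime_without_gaps(self, cfg):
        triples = run_cohort(cfg, 40, 1, base_seed=55)
        for _, tu, tf in triples:
            for traj in (tu, tf):
                prev = 0.0
                for seg in traj.segments:
                    assert seg.t0 == pytest.approx(prev)
                    assert seg.t1 > seg.t0
                    prev = seg.t1
                if traj.segments:
                    assert prev == pytest.approx(traj.events[-1].t)

    def test_zero_horizon(self, cfg):
        p = make_profile(age0=105.0)
        traj = _simulate(p, USUAL, cfg)
        assert [e.kind for e in traj.events] == ["horizon_end"]
        assert traj.survival_days == 0.0

    def test_death_before_confirmation_means_no_diagnosis(self, cfg):
        triples = run_cohort(cfg, 400, 1, base_seed=77)
        unconfirmed = [tf for _, _, tf in triples if not tf.confirmed]
        assert unconfirmed, "expected some work-up deaths"
        for traj in unconfirmed:
            assert traj.diagnosis is None
            assert not traj.scanned
            assert all(e.kind not in ("confirmation", "scan") for e in traj.events)


class TestCommonRandomNumbers:
    def test_reproducible_for_fixed_seed(self, cfg):
        a = run_cohort(cfg, 25, 1, base_seed=5)
        b = run_cohort(cfg, 25, 1, base_seed=5)
        for (pa, ua, fa), (pb, ub, fb) in zip(a, b):
            assert pa == pb
            assert [(e.kind, e.t) for e in ua.events] == [(e.kind, e.t) for e in ub.events]
            assert [(e.kind, e.t) for e in fa.events] == [(e.kind, e.t) for e in fb.events]

    def test_dementia_death_time_shared_across_arms(self, cfg):
        """Treatment has no survival effect in the dementia phase, so under
        common random numbers each dementia patient dies at the same time in
        both arms."""
        triples = run_cohort(cfg, 200, 1, base_seed=9)
        dem = [(tu, tf) for p, tu, tf in triples if p.phase0 == "dementia"]
        assert dem
        for tu, tf in dem:
            assert tu.survival_days == tf.survival_days

    def test_null_scenario_gives_identical_arms(self):
        """With every florbetaben effect switched off and the usual-care
        work-up forced onto the same algorithm and uptake, the two arms
        replay identical trajectories patient by patient."""
        cfg = ScenarioConfig()
        cfg.cohort.p_dementia = 1.0
        cfg.diagnostics.time_reduction = 0.0
        cfg.diagnostics.discontinuation_hr = 1.0
        for a in cfg.diagnostics.algorithms:
            a.usual_care_share = 1.0 if a.algorithm == "clinical+florbetaben_PET" else 0.0
        cfg.treatment.uptake_usual_ad_positive = 1.0
        cfg.treatment.uptake_usual_nonad = 0.0
        # park delayed initiation far beyond any horizon
        cfg.equations["tti_dementia"].intercept = 50.0
        cfg.validate()
        triples = run_cohort(cfg, 80, 1, base_seed=13)
        for _, tu, tf in triples:
            # the explicit scan record only exists in the PET arm; everything
            # else, including the priced test, must replay identically
            events_u = [(e.kind, e.t) for e in tu.events if e.kind != "scan"]
            events_f = [(e.kind, e.t) for e in tf.events if e.kind != "scan"]
            assert events_u == events_f
            su, sf = accumulate(tu, cfg), accumulate(tf, cfg)
            assert su.qaly_total == pytest.approx(sf.qaly_total, rel=1e-12)
            assert su.cost_total == pytest.approx(sf.cost_total, rel=1e-9)


class TestEventTimeOperations:
    def test_institutionalization_median(self, cfg, ad_profile):
        rng = np.random.default_rng(31)
        draws = [time_to_institutionalization(ad_profile, "dementia", 154.0,
                                              False, cfg, rng)
                 for _ in range(100_000)]
        expected = math.exp(9.883 - 0.02 * 82 - 0.001 * 154) * math.log(2) ** 0.933
        assert expected == pytest.approx(2314, abs=5)
        assert np.median(draws) == pytest.approx(expected, rel=0.02)

    def test_treatment_stretches_institutionalization(self, cfg, ad_profile):
        a = time_to_institutionalization(ad_profile, "dementia", 154.0, False,
                                         cfg, np.random.default_rng(8))
        b = time_to_institutionalization(ad_profile, "dementia", 154.0, True,
                                         cfg, np.random.default_rng(8))
        assert b / a == pytest.approx(math.exp(1.079), rel=1e-9)

    def test_shorter_workup_delays_institutionalization(self, cfg, ad_profile):
        a = time_to_institutionalization(ad_profile, "dementia", 254.0, False,
                                         cfg, np.random.default_rng(8))
        b = time_to_institutionalization(ad_profile, "dementia", 154.0, False,
                                         cfg, np.random.default_rng(8))
        assert b / a == pytest.approx(math.exp(0.1), rel=1e-9)

    def test_conversion_median_and_treatment_scaling(self, cfg):
        rng = np.random.default_rng(32)
        base = np.array([time_to_conversion(cfg, rng) for _ in range(50_000)])
        assert np.median(base) == pytest.approx(39.0, rel=0.02)
        rng = np.random.default_rng(32)
        slowed = np.array([time_to_conversion(cfg, rng, hazard_modifier=0.5)
                           for _ in range(50_000)])
        assert np.median(slowed) / np.median(base) == pytest.approx(
            2 ** (1 / 0.952), rel=1e-9)

    def test_hr_one_leaves_conversion_unchanged(self, cfg):
        a = time_to_conversion(cfg, np.random.default_rng(3))
        b = time_to_conversion(cfg, np.random.default_rng(3), hazard_modifier=1.0)
        assert a == b


class TestMortalityCalibration:
    def test_one_year_death_probability(self, cfg):
        """Simulated one-year mortality of an 82-year-old male AD patient
        matches the analytic Gompertz x hazard-ratio value."""
        p = make_profile(male=True)
        hr = mortality_hr("dementia", "AD", cfg)
        assert hr == 2.84
        lam = gompertz_cumulative_hazard(-9.697, 0.087, 82.0, 1.0, hr)
        expected = 1.0 - math.exp(-lam)
        n = 2000
        died = sum(_simulate(p, USUAL, cfg, seed=900, pid=i).survival_days
                   < DAYS_PER_YEAR for i in range(n))
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(died / n - expected) < 4 * se

    def test_predementia_hr_lower(self, cfg):
        assert mortality_hr("predementia", "AD", cfg) == 1.48
        assert mortality_hr("dementia", "VaD", cfg) == 2.69


class TestGompertzCurve:
    def test_inverse_round_trip(self):
        cum, inv = gompertz_curve(-9.697, 0.087, 82.0, hr=2.84)
        for t in (10.0, 365.25, 3652.5):
            assert inv(cum(t)) == pytest.approx(t, rel=1e-9)
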