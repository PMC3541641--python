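"""Discounting, utilities, and cost/QALY accumulation."""

import math

import numpy as np
import pytest

from petdes.config import DAYS_PER_YEAR, ScenarioConfig, get_value, with_value
from petdes.economics import (
    accumulate,
    caregiver_utility,
    discount_factor,
    mean_summary,
    patient_utility,
)
from petdes.engine import Segment, Trajectory

from conftest import make_profile


def _traj(profile, segments, point_costs=(), survival_days=None, confirmed=True):
    t = Trajectory(profile=profile, arm="usual")
    t.segments = list(segments)
    t.point_costs = list(point_costs)
    t.confirmed = confirmed
    t.time_to_dx = 0.0
    t.survival_days = (survival_days if survival_days is not None
                       else (segments[-1].t1 if segments else 0.0))
    return t


def _seg(t0, t1, **overrides):
    base = dict(phase="dementia", severity="mild", mmse=25.0, npi=0.0, adl=0.0,
                iadl=0.0, institutionalized=False, on_treatment=False,
                drug="none", in_workup=False)
    base.update(overrides)
    return Segment(t0=t0, t1=t1, **base)


class TestDiscounting:
    def test_time_zero(self):
        assert discount_factor(0.0, 0.03) == 1.0

    def test_one_year(self):
        assert discount_factor(1.0, 0.03) == pytest.approx(1 / 1.03, rel=1e-12)
        assert discount_factor(1.0, 0.03) == pytest.approx(0.97087, abs=1e-5)

    def test_zero_rate(self):
        for t in (0.0, 1.0, 17.5):
            assert discount_factor(t, 0.0) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1.0, 0.03)


class TestUtilities:
    def test_dementia_ad_patient(self, cfg):
        u = patient_utility("dementia", 21.9, 16.3, False, True, "AD", cfg)
        assert u == pytest.approx(0.408 + 0.219 - 0.0652 + 0.051, abs=1e-9)
        assert u == pytest.approx(0.6128, abs=1e-4)

    def test_predementia_weight(self, cfg):
        assert patient_utility("predementia", 27.5, 2.5, False, True, "prodromalAD",
                               cfg) == 0.82

    def test_nonad_adjustment(self, cfg):
        u_ad = patient_utility("dementia", 21.9, 16.3, False, True, "AD", cfg)
        u_vad = patient_utility("dementia", 21.9, 16.3, False, True, "VaD", cfg)
        assert u_ad - u_vad == pytest.approx(0.006)

    def test_institutionalization_decrement(self, cfg):
        u_home = patient_utility("dementia", 21.9, 16.3, False, True, "AD", cfg)
        u_inst = patient_utility("dementia", 21.9, 16.3, True, True, "AD", cfg)
        assert u_home - u_inst == pytest.approx(0.159)

    def test_caregiver_hand_example(self, cfg):
        p = make_profile(male=True, caregiver_age=79.0, caregiver_male=False)
        u = caregiver_utility(p, npi=16.3, adl=29.7, iadl=29.1, config=cfg)
        expected = 0.90 - 0.003 * 79 + 0.001 - 0.001 * 16.3 - 0.001 * 29.7 - 0.0004 * 29.1
        assert u == pytest.approx(expected, abs=1e-9)
        assert u == pytest.approx(0.6064, abs=1e-3)

    def test_caregiver_npi_coefficient(self, cfg):
        p = make_profile()
        a = caregiver_utility(p, 10.0, 0.0, 0.0, cfg)
        b = caregiver_utility(p, 20.0, 0.0, 0.0, cfg)
        assert a - b == pytest.approx(0.01)

    def test_utilities_clamped(self, cfg):
        assert 0.0 <= patient_utility("dementia", 0.0, 144.0, True, False, "VaD", cfg)
        assert caregiver_utility(make_profile(caregiver_age=120.0), 144.0, 54.0,
                                 56.0, cfg) >= 0.0


class TestAccumulate:
    def test_immediate_death_zero(self, cfg, ad_profile):
        out = accumulate(_traj(ad_profile, [], confirmed=False), cfg)
        assert out.cost_total == 0.0
        assert out.qaly_total == 0.0
        assert out.survival_years == 0.0

    def test_one_year_community_mild_ad_undiscounted(self, ad_profile):
        cfg = ScenarioConfig()
        cfg.discount_rate = 0.0
        seg = _seg(0.0, DAYS_PER_YEAR)
        out = accumulate(_traj(ad_profile, [seg]), cfg)
        assert out.cost_medical == pytest.approx(8315.0)
        assert out.cost_nonmedical == pytest.approx(154.0)
        expected_cg = 2.10 * DAYS_PER_YEAR * 7.25
        assert out.cost_caregiver == pytest.approx(expected_cg)
        assert out.cost_direct_medical == pytest.approx(8469.0)
        assert out.cost_total == pytest.approx(8469.0 + expected_cg)

    def test_institutional_days(self, ad_profile):
        cfg = ScenarioConfig()
        cfg.discount_rate = 0.0
        seg = _seg(0.0, 10.0, institutionalized=True)
        out = accumulate(_traj(ad_profile, [seg]), cfg)
        assert out.cost_institutional == pytest.approx(10 * 373.0)
        assert out.cost_nonmedical == 0.0
        assert out.cost_caregiver == 0.0
        assert out.caregiver_time_years == 0.0

    def test_nonad_cost_fraction(self):
        cfg = ScenarioConfig()
        cfg.discount_rate = 0.0
        vad = make_profile(true_cause="VaD", latent_dementia_cause="VaD")
        seg = _seg(0.0, DAYS_PER_YEAR)
        out = accumulate(_traj(vad, [seg]), cfg)
        assert out.cost_medical == pytest.approx(0.84 * 8315.0)
        # alternative reading: (1 + fraction) x AD cost
        cfg2 = with_value(cfg, "costs.nonad_cost_mode", "one_plus")
        out2 = accumulate(_traj(vad, [seg]), cfg2)
        assert out2.cost_medical == pytest.approx(1.84 * 8315.0)

    def test_drug_cost_accrues_on_treatment(self, ad_profile):
        cfg = ScenarioConfig()
        cfg.discount_rate = 0.0
        seg = _seg(0.0, DAYS_PER_YEAR, on_treatment=True, drug="donepezil")
        out = accumulate(_traj(ad_profile, [seg]), cfg)
        assert out.cost_drugs == pytest.approx(7.79 * DAYS_PER_YEAR)

    def test_workup_rate_applies_during_workup(self, ad_profile):
        cfg = ScenarioConfig()
        cfg.discount_rate = 0.0
        seg = _seg(0.0, DAYS_PER_YEAR, in_workup=True)
        out = accumulate(_traj(ad_profile, [seg]), cfg)
        assert out.cost_workup == pytest.approx(5120.0)

    def test_qaly_closed_form_constant_state(self, ad_profile):
        """QALYs for a constant state equal utility x continuous annuity."""
        cfg = ScenarioConfig()
        years = 10.0
        seg = _seg(0.0, years * DAYS_PER_YEAR, mmse=21.9, npi=16.3)
        out = accumulate(_traj(ad_profile, [seg]), cfg)
        u = patient_utility("dementia", 21.9, 16.3, False, True, "AD", cfg)
        rho = math.log(1.03)
        annuity = (1 - math.exp(-rho * years)) / rho
        assert out.qaly_patient == pytest.approx(u * annuity, rel=1e-9)

    def test_discounting_bounds(self, ad_profile):
        seg = _seg(0.0, 5 * DAYS_PER_YEAR)
        cfg0 = ScenarioConfig()
        cfg0.discount_rate = 0.0
        cfg3 = ScenarioConfig()
        undisc = accumulate(_traj(ad_profile, [seg]), cfg0)
        disc = accumulate(_traj(ad_profile, [seg]), cfg3)
        assert disc.cost_total < undisc.cost_total
        assert disc.qaly_total < undisc.qaly_total

    def test_price_monotonicity(self, ad_profile):
        """Raising any cost input never lowers the total."""
        segs = [_seg(0.0, DAYS_PER_YEAR, in_workup=True, on_treatment=True,
                     drug="donepezil"),
                _seg(DAYS_PER_YEAR, 2 * DAYS_PER_YEAR, severity="severe",
                     institutionalized=True)]
        base_cfg = ScenarioConfig()
        base = accumulate(_traj(ad_profile, segs), base_cfg).cost_total
        for path in ("costs.institutional_per_day", "costs.workup_ad",
                     "costs.caregiver_wage_per_hour"):
            cfg = with_value(base_cfg, path, 2.0 * get_value(base_cfg, path))
            up = accumulate(_traj(ad_profile, segs), cfg).cost_total
            assert up >= base

    def test_point_costs_discounted_at_event_time(self, ad_profile):
        cfg = ScenarioConfig()
        seg = _seg(0.0, DAYS_PER_YEAR)
        t_scan = 0.5 * DAYS_PER_YEAR
        out = accumulate(_traj(ad_profile, [seg], point_costs=[(t_scan, "test", 2300.0)]), cfg)
        assert out.cost_tests == pytest.approx(2300.0 * 1.03 ** -0.5, rel=1e-9)

    def test_gap_detection(self, cfg, ad_profile):
        segs = [_seg(0.0, 10.0), _seg(20.0, 30.0)]
        with pytest.raises(ValueError, match="gap"):
            accumulate(_traj(ad_profile, segs), cfg)

    def test_category_additivity(self, cfg, ad_profile):
        segs = [_seg(0.0, DAYS_PER_YEAR, in_workup=True)]
        out = accumulate(_traj(ad_profile, segs), cfg)
        assert out.cost_total == pytest.approx(out.cost_direct_medical
                                               + out.cost_caregiver, rel=1e-9)

    def test_payer_perspective_excludes_caregiver_cost(self, ad_profile):
        cfg = ScenarioConfig()
        cfg.include_caregiver_costs = False
        seg = _seg(0.0, DAYS_PER_YEAR)
        out = accumulate(_traj(ad_profile, [seg]), cfg)
        assert out.cost_total == pytest.approx(out.cost_direct_medical, rel=1e-12)


class TestMeanSummary:
    def test_conditional_means(self, cfg, ad_profile):
        t1 = _traj(ad_profile, [_seg(0.0, DAYS_PER_YEAR)], confirmed=True)
        t1.time_to_dx = 152.2
        t2 = _traj(ad_profile, [_seg(0.0, DAYS_PER_YEAR)], confirmed=False)
        s1, s2 = accumulate(t1, cfg), accumulate(t2, cfg)
        m = mean_summary([s1, s2])
        assert m.confirmed == 0.5
        assert m.time_to_dx_months == pytest.approx(s1.time_to_dx_months)
        assert m.survival_years == pytest.approx(1.0)
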