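"""Discounting, utilities, cost accrual and incremental measures."""

import numpy as np
import pytest

import apixvka as av
from apixvka.engine import run_trace
from apixvka.outcomes import (ArmResults, cycle_costs, discount_factor,
                              incremental, state_utility, summarize)
from apixvka.scenarios import ScenarioSpec, build_schedule
from apixvka.states import HealthState, DEAD
from tests.conftest import make_degenerate_config


class TestDiscounting:
    def test_examples(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(4, 0.03) == pytest.approx(1 / 1.03)
        assert discount_factor(40, 0.03) == pytest.approx(1.03 ** -10)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestUtilities:
    def test_baseline_examples(self, config):
        c = config.utilities.baseline_coeffs
        assert av.baseline_utility(69.9, 0.71, c) == pytest.approx(0.8046,
                                                                   abs=2e-4)
        assert av.baseline_utility(0, 0, c) == pytest.approx(0.9454933)
        assert av.baseline_utility(50, 1, c) == pytest.approx(0.886575,
                                                              abs=1e-6)

    def test_state_utility_examples(self, config):
        free = HealthState(phase="event_free", on_treatment=True)
        assert state_utility(free, 69.9, config) == pytest.approx(0.8046,
                                                                  abs=2e-4)
        assert state_utility(DEAD, 69.9, config) == 0.0
        post_mi = HealthState(history=("MI",), phase="post_acute",
                              on_treatment=True)
        assert state_utility(post_mi, 69.9, config) == pytest.approx(0.70644,
                                                                     abs=3e-4)

    def test_joint_post_state_multiplies_both_ratios(self, config):
        joint = HealthState(history=("IS", "ICH"), phase="post_acute",
                            on_treatment=False)
        expect = av.baseline_utility(69.9, 0.71,
                                     config.utilities.baseline_coeffs)
        expect *= 0.825 * 0.849
        assert state_utility(joint, 69.9, config) == pytest.approx(expect)

    def test_short_term_intensity_weighting(self, config):
        free = HealthState(phase="event_free", on_treatment=True)
        u0 = state_utility(free, 69.9, config)
        u = state_utility(free, 69.9, config,
                          short_term_intensities=[0.5, 0.0, 0.0])
        assert u == pytest.approx(u0 * (1 - 0.5 * (1 - 0.988)))


class TestAccrual:
    def test_annuity_closed_form(self, config):
        """Zero mortality, utility 1: LY and QALY equal the discrete
        annuity of 0.25-year payments at 3%."""
        cfg = make_degenerate_config(config, utility_one=True)
        sched = build_schedule(ScenarioSpec(), 40)
        res = summarize(run_trace(cfg, "apixaban", sched, horizon=40), cfg)
        annuity = 0.25 * sum(1.03 ** (-0.25 * k) for k in range(40))
        assert res.ly == pytest.approx(annuity, abs=1e-9)
        assert res.qaly == pytest.approx(annuity, abs=1e-9)

    def test_undiscounted_horizon(self, config):
        cfg = make_degenerate_config(config, utility_one=True,
                                     zero_discount=True)
        sched = build_schedule(ScenarioSpec(), 40)
        res = summarize(run_trace(cfg, "apixaban", sched, horizon=40), cfg)
        assert res.ly == pytest.approx(10.0, abs=1e-9)

    def test_mono_phase_drug_cost(self, config):
        """With no events and everyone on treatment, the only cost in a
        monotherapy cycle is the OAC cost, discounted."""
        cfg = make_degenerate_config(config, event_free_start=True)
        sched = build_schedule(ScenarioSpec(), 40)
        tr = run_trace(cfg, "apixaban", sched, horizon=40)
        comp = cycle_costs(tr, 5, cfg)
        assert comp["treatment"] == pytest.approx(
            173.49 * discount_factor(5, 0.03))
        for key in ("monitoring", "acute", "maintenance"):
            assert comp[key] == 0.0

    def test_blend_phase_drug_cost(self, config):
        """The blended phase charges OAC + weighted P2Y12 + half aspirin."""
        cfg = make_degenerate_config(config, event_free_start=True)
        sched = build_schedule(ScenarioSpec(), 40)
        tr = run_trace(cfg, "vka", sched, horizon=40)
        comp = cycle_costs(tr, 0, cfg)
        expect = 13.70 + 64.8594 + 0.5 * 3.58
        assert comp["treatment"] == pytest.approx(expect, abs=1e-3)
        assert comp["monitoring"] == pytest.approx(4.5 * 7.05)

    def test_off_treatment_pays_nothing(self, config):
        """A fully discontinued cohort accrues no treatment or monitoring
        cost."""
        cfg = make_degenerate_config(config)
        for arm in av.ARMS:
            cfg.discontinuation.per_cycle_unrelated[arm] = 1.0
        sched = build_schedule(ScenarioSpec(), 40)
        res = summarize(run_trace(cfg, "vka", sched, horizon=40), cfg)
        # only cycle 0 is on treatment; everything after costs nothing
        assert res.treatment_cost == pytest.approx(
            13.70 + 64.8594 + 0.5 * 3.58, abs=1e-3)
        assert res.monitoring_cost == pytest.approx(4.5 * 7.05)
        assert res.time_off_treatment > 0.9 * res.ly

    def test_incident_event_acute_cost(self, config, base_case):
        """Acute costs in a cycle equal incident events times DRG costs."""
        sched = build_schedule(ScenarioSpec(), config.horizon)
        tr = run_trace(config, "apixaban", sched)
        comp = cycle_costs(tr, 10, config)
        lt = np.array([config.costs.acute[e] for e in av.LONG_TERM_EVENTS])
        st = np.array([config.costs.acute[e] for e in av.SHORT_TERM_EVENTS])
        expect = (tr.incident_lt[10] @ lt + tr.incident_st[10] @ st)
        expect *= discount_factor(10, 0.03)
        assert comp["acute"] == pytest.approx(expect)

    def test_societal_equals_payer_without_indirect_rows(self, config):
        cfg = config.copy()
        cfg.costs.societal_acute = {e: 0.0 for e in cfg.costs.societal_acute}
        cfg.costs.societal_monthly = {e: 0.0 for e in cfg.costs.societal_monthly}
        base = av.run_base_case(cfg)
        for arm in (base.apixaban, base.vka):
            assert arm.total_cost_societal == pytest.approx(arm.total_cost_payer)

    def test_qaly_bounded_by_ly(self, base_case):
        assert base_case.apixaban.qaly <= base_case.apixaban.ly
        assert base_case.vka.qaly <= base_case.vka.ly

    def test_discounting_reduces_totals(self, config):
        cfg = config.copy()
        cfg.discount_rate_annual = 0.0
        undisc = av.run_base_case(cfg)
        disc = av.run_base_case(config)
        for a, b in ((undisc.apixaban, disc.apixaban),
                     (undisc.vka, disc.vka)):
            assert a.ly >= b.ly and a.qaly >= b.qaly
            assert a.total_cost_payer >= b.total_cost_payer
            assert a.treatment_cost >= b.treatment_cost


class TestIncremental:
    def _arm(self, cost, qaly, ly=10.0):
        return ArmResults(arm="x", treatment_cost=cost, monitoring_cost=0,
                          acute_event_cost=0, maintenance_cost=0,
                          indirect_acute_cost=0, indirect_maintenance_cost=0,
                          ly=ly, qaly=qaly, events_per_100={},
                          time_on_treatment=0, time_off_treatment=0)

    def test_dominant_arithmetic(self):
        inc = incremental(self._arm(1000, 5.1), self._arm(2000, 5.0), 20000)
        assert inc.inmb == pytest.approx(3000)
        assert inc.inhb == pytest.approx(0.15)
        assert inc.dominance == "dominant"

    def test_inhb_is_inmb_over_wtp(self, base_case):
        inc = base_case.increment
        assert inc.inhb == pytest.approx(inc.inmb / inc.wtp)

    def test_cost_effective_quadrant(self):
        inc = incremental(self._arm(3000, 5.1), self._arm(2000, 5.0), 20000)
        assert inc.icer == pytest.approx(10000)
        assert inc.dominance == "cost_effective"

    def test_dominated_quadrant(self):
        inc = incremental(self._arm(3000, 4.9), self._arm(2000, 5.0), 20000)
        assert inc.dominance == "dominated"

    def test_equal_arms_zero(self, config):
        eq = av.equal_arm_config(config)
        base = av.run_base_case(eq)
        assert base.increment.d_cost == 0.0
        assert base.increment.d_ly == 0.0
        assert base.increment.d_qaly == 0.0
        assert base.increment.inmb == 0.0
        assert base.increment_societal.d_cost == 0.0
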