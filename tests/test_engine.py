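"""Transition-probability construction and cohort propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import apixvka as av
from apixvka.engine import (aging_multiplier, background_death_prob,
                            compile_arm, event_fatality,
                            rate_to_competing_probs, run_trace)
from apixvka.scenarios import ScenarioSpec, build_schedule
from apixvka.states import HealthState
from tests.conftest import make_degenerate_config


class TestRateConversion:
    def test_single_rate(self):
        p, stay = rate_to_competing_probs([6.25], 0.25)
        assert p[0] == pytest.approx(0.0155036, abs=1e-6)
        assert p[0] + stay == pytest.approx(1.0)

    def test_two_equal_rates(self):
        p, _ = rate_to_competing_probs([4.0, 4.0], 0.25)
        assert p[0] == pytest.approx(0.0099007, abs=1e-6)
        assert p[0] == pytest.approx(p[1])

    def test_zero_rates(self):
        p, stay = rate_to_competing_probs([0.0, 0.0, 0.0], 0.25)
        assert stay == 1.0 and np.all(p == 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rate_to_competing_probs([-1.0], 0.25)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 60), min_size=1, max_size=7),
           st.floats(0.01, 1.0))
    def test_probabilities_partition_unity(self, rates, t):
        p, stay = rate_to_competing_probs(rates, t)
        assert np.all(p >= 0) and stay >= 0
        assert p.sum() + stay == pytest.approx(1.0, abs=1e-12)


class TestHazardPieces:
    def test_aging_one_decade(self, config):
        assert aging_multiplier("OMB", 80.4, 70.4, config.hrs) == pytest.approx(1.97)

    def test_aging_at_reference(self, config):
        assert aging_multiplier("IS", 70.4, 70.4, config.hrs) == 1.0

    def test_aging_half_decade(self, config):
        assert aging_multiplier("OMB", 75.4, 70.4, config.hrs) == pytest.approx(
            1.97 ** 0.5, abs=1e-5)

    @pytest.mark.parametrize("event,age,expected", [
        ("IS", 70, 0.109),      # flat band
        ("ICH", 80, 0.268),     # 75-85 band
        ("MI", 55, 0.071),      # clamps to the lowest (60-70) band
        ("MI", 85, 0.316),      # falls in the open-ended 80+ band
        ("OMB", 95, 0.020),
    ])
    def test_event_fatality(self, config, event, age, expected):
        assert event_fatality(event, age, config.fatality) == pytest.approx(expected)

    def test_background_death(self):
        # closed form: 1 - (1 - qx)^(0.25 * HR)
        assert background_death_prob(0.02, 2.6) == pytest.approx(
            1.0 - 0.98 ** 0.65, abs=1e-12)
        assert background_death_prob(0.02, 2.6) == pytest.approx(0.0130459,
                                                                 abs=1e-6)
        assert background_death_prob(0.0, 5.0) == 0.0
        assert background_death_prob(0.02, 1.0) == pytest.approx(0.0050379,
                                                                 abs=1e-6)


class TestTransitionRows:
    def test_dead_absorbing(self, config, space):
        sched = build_schedule(ScenarioSpec(), config.horizon)
        c = compile_arm(config, "apixaban", sched)
        assert c.P[:, space.dead, space.dead].min() == 1.0

    def test_zero_dynamics_identity(self, config, space):
        """With zero rates/mortality/discontinuation states persist, except
        acute states which still progress to post-acute."""
        cfg = make_degenerate_config(config)
        sched = build_schedule(ScenarioSpec(), 40)
        c = compile_arm(cfg, "vka", sched, horizon=40)
        for i, s in enumerate(space.states[:space.n_alive]):
            dest = space.prog_on[i] if s.on_treatment else space.prog_off[i]
            assert c.P[0, i, dest] == pytest.approx(1.0, abs=1e-12)

    def test_rows_sum_to_one(self, config):
        sched = build_schedule(ScenarioSpec(), config.horizon)
        for arm in av.ARMS:
            c = compile_arm(config, arm, sched)
            assert np.allclose(c.P.sum(axis=2), 1.0, atol=1e-12)

    def test_no_flow_off_to_on(self, config, space):
        """Off-treatment occupancy can never return to any on-treatment
        state (discontinuation is permanent)."""
        sched = build_schedule(ScenarioSpec(), config.horizon)
        c = compile_arm(config, "apixaban", sched)
        off_rows = ~space.on_mask
        on_cols = np.concatenate([space.on_mask, [False]])
        assert np.all(c.P[:, :space.n_alive, :][:, off_rows][:, :, on_cols] == 0)

    def test_event_free_mono_is_probability(self, config, space):
        """p(IS acute) from the event-free on-treatment state in the
        monotherapy phase, verified against the brute-force builder."""
        sched = build_schedule(ScenarioSpec(), config.horizon)
        c = compile_arm(config, "apixaban", sched)
        naive = av.naive_transition_matrix(config, "apixaban", sched, 2)
        i = space.index[HealthState(phase="event_free", on_treatment=True)]
        j_on = space.index[HealthState(history=("IS",), phase="acute",
                                       acute_event="IS", on_treatment=True)]
        j_off = space.index[HealthState(history=("IS",), phase="acute",
                                        acute_event="IS", on_treatment=False)]
        got = c.P[2, i, j_on] + c.P[2, i, j_off]
        assert got == pytest.approx(naive[i, j_on] + naive[i, j_off],
                                    rel=1e-12)
        # sanity envelope: competing-risk splitting and the mortality/fatality
        # factors keep it just below the single-cause bound
        single = 1.0 - np.exp(-0.0097 * 0.25)
        assert 0.75 * single < got < single


class TestTrace:
    def test_conservation_and_absorption(self, config):
        sched = build_schedule(ScenarioSpec(), config.horizon)
        for arm in av.ARMS:
            tr = run_trace(config, arm, sched)
            assert np.allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-10)
            dead = tr.occupancy[:, tr.space.dead]
            assert np.all(np.diff(dead) >= -1e-15)
            assert dead[-1] > 0.9     # near-full absorption by age 100

    def test_initial_split(self, config, base_case):
        sched = build_schedule(ScenarioSpec(), config.horizon)
        tr = run_trace(config, "apixaban", sched)
        sp = tr.space
        post_mi = sp.index[HealthState(history=("MI",), phase="post_acute",
                                       on_treatment=True)]
        free = sp.index[HealthState(phase="event_free", on_treatment=True)]
        assert tr.occupancy[0, post_mi] == pytest.approx(0.612)
        assert tr.occupancy[0, free] == pytest.approx(0.388)

    def test_zero_dynamics_constant_occupancy(self, config):
        cfg = make_degenerate_config(config)
        sched = build_schedule(ScenarioSpec(), 40)
        tr = run_trace(cfg, "apixaban", sched, horizon=40)
        assert np.allclose(tr.occupancy, tr.occupancy[0], atol=1e-12)
        assert np.all(tr.incident_lt == 0) and np.all(tr.incident_st == 0)

    def test_monotonicity_in_rates(self, config):
        """Raising one arm's IS rate weakly increases its IS count and
        weakly decreases its life years."""
        sched = build_schedule(ScenarioSpec(), config.horizon)
        base_tr = run_trace(config, "vka", sched)
        base = av.summarize(base_tr, config)
        cfg = config.copy()
        for phase in ("triple_or_dual", "mono"):
            cfg.rates.rates[(phase, "vka")]["IS"] *= 2.0
        up = av.summarize(run_trace(cfg, "vka", sched), cfg)
        assert up.events_per_100["IS"] > base.events_per_100["IS"]
        assert up.ly < base.ly

    def test_trace_export_frames(self, config):
        sched = build_schedule(ScenarioSpec(), 8)
        tr = run_trace(config, "apixaban", sched, horizon=8)
        df = tr.to_frame()
        assert df.shape == (9, 55)
        ev = tr.events_frame()
        assert list(ev.columns) == list(av.LONG_TERM_EVENTS + av.SHORT_TERM_EVENTS)
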