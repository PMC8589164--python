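"""DSA bounds and tornado, PSA sampling distributions, CEAC."""

import numpy as np
import pytest

import apixvka as av
from apixvka.parameters import ParamMeta
from apixvka.uncertainty import (PSASampleSet, _lognormal_sigma, ceac,
                                 dsa_bounds, run_dsa, run_psa,
                                 sample_parameter)


class TestDSABounds:
    def test_ci_bounds(self, config):
        b = dsa_bounds("hr.aging.OMB", config)
        assert (b.low, b.high) == (1.79, 2.16)
        assert b.source == "ci"

    def test_pct10_bounds(self, config):
        b = dsa_bounds("cost.drug_cycle.apixaban", config)
        assert b.low == pytest.approx(156.141)
        assert b.high == pytest.approx(190.839)
        assert b.source == "pct10"

    def test_se_bounds(self, config):
        b = dsa_bounds("disc.event.ICH", config)
        assert b.low == pytest.approx(0.4230, abs=2e-4)
        assert b.high == pytest.approx(0.6930, abs=2e-4)
        assert b.source == "se"

    def test_unknown_parameter(self, config):
        with pytest.raises(KeyError):
            dsa_bounds("nope.nope", config)


class TestDSARuns:
    def test_zero_swing_identity(self, config, base_case):
        """A parameter whose bounds both sit at the base value reproduces
        the base-case INMB exactly."""
        cfg = config.copy()
        base = av.get_param(cfg, "cost.acute.IS")
        cfg.param_meta["cost.acute.IS"] = ParamMeta(
            pid="cost.acute.IS", dist="gamma", value=base, ci=(base, base))
        entries = run_dsa(cfg, pids=["cost.acute.IS"])
        e = entries[0]
        assert e.swing == 0.0
        assert e.inmb_low == pytest.approx(base_case.increment.inmb, abs=1e-6)

    def test_swing_direction(self, config):
        """A higher VKA intracranial-bleed rate makes apixaban look better
        (larger INMB), and repeat runs are deterministic."""
        pid = "rate.mono.vka.ICH"
        e = run_dsa(config, pids=[pid])[0]
        assert e.inmb_high > e.inmb_low
        again = run_dsa(config, pids=[pid])[0]
        assert again.inmb_low == e.inmb_low and again.inmb_high == e.inmb_high

    def test_tornado_sorted_and_influential(self, config):
        pids = ["disc.unrelated.apixaban", "disc.unrelated.vka",
                "util.post.OMB.ratio", "cost.drug_cycle.apixaban",
                "cost.maintenance.ICH", "rate.mono.vka.ICH"]
        entries = run_dsa(config, pids=pids)
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)
        assert all(np.isfinite(s) for s in swings)
        # apixaban stays dominant (INMB > 0) at every bound tested
        for e in entries:
            assert e.inmb_low > 0 and e.inmb_high > 0


class TestSampling:
    def test_gamma_moment_matching(self):
        meta = ParamMeta(pid="x", dist="gamma", value=6.25, se=0.02)
        rng = np.random.default_rng(0)
        draws = np.array([sample_parameter(meta, 6.25, rng)
                          for _ in range(10000)])
        assert draws.mean() == pytest.approx(6.25, abs=3 * 0.02 / 100)
        assert draws.std() == pytest.approx(0.02, rel=0.05)

    def test_beta_moment_matching(self):
        meta = ParamMeta(pid="x", dist="beta", value=0.25, se=0.025)
        rng = np.random.default_rng(1)
        draws = np.array([sample_parameter(meta, 0.25, rng)
                          for _ in range(10000)])
        assert draws.mean() == pytest.approx(0.25, abs=3 * 0.025 / 100)
        assert draws.std() == pytest.approx(0.025, rel=0.05)
        assert np.all((draws > 0) & (draws < 1))

    def test_lognormal_sigma_from_ci(self):
        meta = ParamMeta(pid="x", dist="lognormal", value=0.26,
                         ci=(0.18, 0.37))
        assert _lognormal_sigma(meta) == pytest.approx(0.18381, abs=1e-5)
        rng = np.random.default_rng(2)
        draws = np.array([sample_parameter(meta, 0.26, rng)
                          for _ in range(10000)])
        assert np.median(draws) == pytest.approx(0.26, rel=0.02)
        assert np.all(draws > 0)

    def test_zero_se_degenerate(self):
        meta = ParamMeta(pid="x", dist="gamma", value=5.0, se=0.0)
        rng = np.random.default_rng(3)
        assert sample_parameter(meta, 5.0, rng) == 5.0

    def test_dirichlet_simplex(self, config):
        meta = config.param_meta["p2y12.apixaban"]
        rng = np.random.default_rng(4)
        draws = np.array([sample_parameter(meta, meta.value, rng,
                                           config.dirichlet_effective_count)
                          for _ in range(2000)])
        assert np.allclose(draws.sum(axis=1), 1.0)
        assert draws[:, 0].mean() == pytest.approx(0.934, abs=0.002)

    def test_truncated_normal_age(self, config):
        meta = config.param_meta["cohort.start_age"]
        rng = np.random.default_rng(5)
        draws = np.array([sample_parameter(meta, 69.9, rng)
                          for _ in range(2000)])
        assert np.all((draws >= 40) & (draws <= 90))
        assert draws.mean() == pytest.approx(69.9, abs=0.02)

    def test_drawn_configs_validate(self, config):
        rng = np.random.default_rng(6)
        for _ in range(10):
            cfg, _ = av.draw_psa_config(config, rng)
            cfg.validate()


class TestPSARuns:
    def test_determinism(self, config):
        a = run_psa(config, n=5, seed=11)
        b = run_psa(config, n=5, seed=11)
        assert np.array_equal(a.d_cost, b.d_cost)
        assert np.array_equal(a.d_qaly, b.d_qaly)

    def test_degenerate_draws_equal_base(self, config, base_case):
        """With every SE forced to zero (and CIs collapsed) each draw is
        the base case and the whole cloud sits in its quadrant."""
        cfg = config.copy()
        for pid, m in cfg.param_meta.items():
            cfg.param_meta[pid] = ParamMeta(pid=pid, dist=m.dist,
                                            value=m.value, se=0.0)
        ps = run_psa(cfg, n=4, seed=0)
        assert np.allclose(ps.d_cost, base_case.increment.d_cost)
        assert np.allclose(ps.d_qaly, base_case.increment.d_qaly)
        assert ps.quadrant_shares()["SE_dominant"] == 1.0

    def test_quadrant_shares_sum_to_one(self, config):
        ps = run_psa(config, n=20, seed=9)
        assert sum(ps.quadrant_shares().values()) == pytest.approx(1.0)


class TestCEAC:
    def _samples(self, d_cost, d_qaly, wtp=20000.0):
        d_cost = np.asarray(d_cost, float)
        d_qaly = np.asarray(d_qaly, float)
        return PSASampleSet(n=len(d_cost), seed=0, wtp=wtp, d_cost=d_cost,
                            d_ly=d_qaly, d_qaly=d_qaly)

    def test_wtp_zero_limit(self):
        s = self._samples([-1, -1, 2, 3], [0.1, -0.2, 0.3, 0.4])
        assert ceac(s, [0.0])[0] == 0.5     # fraction with negative cost

    def test_large_wtp_limit(self):
        s = self._samples([-1, -1, 2, 3], [0.1, -0.2, 0.3, 0.4])
        assert ceac(s, [1e12])[0] == 0.75   # fraction with positive QALYs

    def test_all_dominant_curve_is_one(self):
        s = self._samples([-5, -1], [0.1, 0.2])
        grid = np.linspace(0, 50000, 6)
        assert np.all(ceac(s, grid) == 1.0)

    def test_ties_count_half(self):
        s = self._samples([0.0], [0.0])
        assert ceac(s, [20000.0])[0] == 0.5

    def test_empty_grid_rejected(self):
        s = self._samples([-1], [0.1])
        with pytest.raises(ValueError):
            ceac(s, [])
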