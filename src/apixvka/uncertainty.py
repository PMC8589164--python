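"""One-way deterministic and probabilistic sensitivity analyses.

DSA varies each registered parameter to its 95% CI bounds (else mean
± 1.96 SE, else ±10% of the base value) one at a time and ranks parameters
by the absolute swing in incremental net monetary benefit.

PSA samples every registered parameter from its family — gamma for rates
and costs, beta for probabilities and utility ratios, lognormal for hazard
ratios, Dirichlet for the P2Y12 mix, truncated normal for age — via moment
matching, re-solves both arms per draw, and summarizes the resulting cloud
on the cost-effectiveness plane (quadrant shares, CEAC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .outcomes import incremental
from .parameters import ModelConfig, ParamMeta, get_param, set_param
from .scenarios import ScenarioSpec, run_scenario

_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# DSA
# ---------------------------------------------------------------------------

@dataclass
class DSABound:
    pid: str
    base: float
    low: float
    high: float
    source: str                # ci | se | pct10


def dsa_bounds(pid: str, config: ModelConfig) -> DSABound:
    """Low/high values for one parameter."""
    meta = config.param_meta.get(pid)
    if meta is None:
        raise KeyError(f"unknown parameter id {pid}")
    base = float(get_param(config, pid))
    if meta.ci is not None:
        low, high = float(meta.ci[0]), float(meta.ci[1])
        source = "ci"
    elif meta.se is not None and meta.se > 0:
        low, high = base - _Z95 * meta.se, base + _Z95 * meta.se
        source = "se"
    else:
        low, high = 0.9 * base, 1.1 * base
        source = "pct10"
    if meta.dist == "beta":
        low, high = max(low, 0.0), min(high, 1.0)
    if meta.dist in ("gamma", "lognormal"):
        low = max(low, 0.0 if meta.dist == "gamma" else 1e-12)
    if not low <= base <= high:
        raise ValueError(f"{pid}: bounds ({low}, {high}) do not bracket {base}")
    return DSABound(pid=pid, base=base, low=low, high=high, source=source)


@dataclass
class TornadoEntry:
    pid: str
    low: float
    high: float
    inmb_low: float
    inmb_high: float
    d_qaly_low: float
    d_qaly_high: float
    d_cost_low: float
    d_cost_high: float

    @property
    def swing(self) -> float:
        return abs(self.inmb_high - self.inmb_low)


def run_dsa(config: ModelConfig, pids=None,
            spec: ScenarioSpec | None = None) -> list:
    """One-way DSA over the registered parameters, sorted by INMB swing."""
    spec = spec or ScenarioSpec()
    if pids is None:
        pids = [pid for pid, m in config.param_meta.items() if m.in_dsa]
    entries = []
    for pid in pids:
        b = dsa_bounds(pid, config)
        res = {}
        for side, value in (("low", b.low), ("high", b.high)):
            cfg = config.copy()
            set_param(cfg, pid, value)
            res[side] = run_scenario(cfg, spec)
        entries.append(TornadoEntry(
            pid=pid, low=b.low, high=b.high,
            inmb_low=res["low"].increment.inmb,
            inmb_high=res["high"].increment.inmb,
            d_qaly_low=res["low"].increment.d_qaly,
            d_qaly_high=res["high"].increment.d_qaly,
            d_cost_low=res["low"].increment.d_cost,
            d_cost_high=res["high"].increment.d_cost))
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def tornado_frame(entries, top: int | None = 10):
    import pandas as pd
    rows = [{"parameter": e.pid, "low": e.low, "high": e.high,
             "inmb_low": e.inmb_low, "inmb_high": e.inmb_high,
             "swing": e.swing} for e in entries[:top]]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PSA sampling
# ---------------------------------------------------------------------------

def _lognormal_sigma(meta: ParamMeta) -> float:
    if meta.ci is not None:
        lo, hi = meta.ci
        if hi <= lo:
            return 0.0
        return (math.log(hi) - math.log(lo)) / (2 * _Z95)
    # no CI reported: fall back on +/-10% bounds treated as a 95% interval
    return (math.log(1.1) - math.log(0.9)) / (2 * _Z95)


def sample_parameter(meta: ParamMeta, base, rng: np.random.Generator,
                     dirichlet_n: float = 2306.0):
    """One draw from a parameter's PSA distribution (moment matching).

    An explicit SE of 0 makes the distribution degenerate: the mean is
    returned unchanged (an SE of None means "not printed" and falls back
    on the ±10% convention instead).
    """
    if meta.se == 0:
        return base
    if meta.dist == "gamma":
        m = float(base)
        if m <= 0:
            return m
        se = meta.se if meta.se else 0.1 * m / _Z95
        if se <= 0:
            return m
        v = se * se
        shape, rate = m * m / v, m / v
        return float(rng.gamma(shape, 1.0 / rate))
    if meta.dist == "beta":
        m = float(base)
        se = meta.se if meta.se is not None else 0.1 * m / _Z95
        if se <= 0 or m <= 0 or m >= 1:
            return m
        v = se * se
        nu = m * (1 - m) / v - 1.0
        if nu <= 0:        # variance too large for a proper beta; keep mean
            return m
        return float(rng.beta(m * nu, (1 - m) * nu))
    if meta.dist == "lognormal":
        m = float(base)
        sigma = _lognormal_sigma(meta)
        if sigma <= 0:
            return m
        return float(rng.lognormal(math.log(m), sigma))
    if meta.dist == "normal":
        m = float(base)
        se = meta.se or 0.0
        if se <= 0:
            return m
        lo, hi = meta.bounds if meta.bounds else (-np.inf, np.inf)
        for _ in range(100):
            x = float(rng.normal(m, se))
            if lo <= x <= hi:
                return x
        return float(min(max(m, lo), hi))
    if meta.dist == "dirichlet":
        shares = np.asarray(base, dtype=float)
        alpha = shares * dirichlet_n
        if np.any(alpha <= 0):
            return tuple(shares)
        return tuple(rng.dirichlet(alpha))
    raise ValueError(f"unknown distribution {meta.dist}")


def draw_psa_config(config: ModelConfig, rng: np.random.Generator
                    ) -> tuple[ModelConfig, dict]:
    """Sample every registered parameter; returns the config and the draws."""
    cfg = config.copy()
    drawn = {}
    for pid, meta in config.param_meta.items():
        base = get_param(config, pid)
        value = sample_parameter(meta, base, rng,
                                 config.dirichlet_effective_count)
        set_param(cfg, pid, value)
        drawn[pid] = value
    return cfg, drawn


# ---------------------------------------------------------------------------
# PSA runs, CE plane, CEAC
# ---------------------------------------------------------------------------

@dataclass
class PSASampleSet:
    """Per-draw increments from a probabilistic sensitivity analysis."""

    n: int
    seed: int
    wtp: float
    d_cost: np.ndarray
    d_ly: np.ndarray
    d_qaly: np.ndarray
    draws: dict = field(default_factory=dict, repr=False)   # pid -> values

    @property
    def inmb(self) -> np.ndarray:
        return self.wtp * self.d_qaly - self.d_cost

    def quadrant_shares(self) -> dict:
        """Cost-effectiveness plane quadrant shares (sum to 1)."""
        dq, dc = self.d_qaly, self.d_cost
        se = np.mean((dq > 0) & (dc < 0))
        ne = (dq > 0) & (dc >= 0)
        ne_below = np.mean(ne & (dc <= self.wtp * dq))
        ne_above = np.mean(ne & (dc > self.wtp * dq))
        nw = np.mean((dq <= 0) & (dc >= 0))
        sw = np.mean((dq <= 0) & (dc < 0))
        return {"SE_dominant": float(se),
                "NE_below_wtp": float(ne_below),
                "NE_above_wtp": float(ne_above),
                "NW_dominated": float(nw),
                "SW_tradeoff": float(sw)}

    def summary(self) -> dict:
        q = self.quadrant_shares()
        return {
            "n": self.n,
            "mean_d_cost": float(self.d_cost.mean()),
            "mean_d_ly": float(self.d_ly.mean()),
            "mean_d_qaly": float(self.d_qaly.mean()),
            "share_cost_effective_at_wtp": float(np.mean(self.inmb > 0)),
            **q,
        }

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"d_cost": self.d_cost, "d_ly": self.d_ly,
                             "d_qaly": self.d_qaly, "inmb": self.inmb})


def run_psa(config: ModelConfig, n: int = 1000, seed: int = 1,
            spec: ScenarioSpec | None = None,
            keep_draws: bool = False) -> PSASampleSet:
    """n PSA iterations: sample, solve both arms, record the increments."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or ScenarioSpec()
    rng = np.random.default_rng(seed)
    d_cost = np.empty(n)
    d_ly = np.empty(n)
    d_qaly = np.empty(n)
    draws: dict = {}
    for i in range(n):
        cfg, drawn = draw_psa_config(config, rng)
        res = run_scenario(cfg, spec)
        inc = (res.increment_societal if (spec.perspective or config.perspective)
               == "societal" else res.increment)
        d_cost[i] = inc.d_cost
        d_ly[i] = inc.d_ly
        d_qaly[i] = inc.d_qaly
        if keep_draws:
            for pid, v in drawn.items():
                if np.isscalar(v):
                    draws.setdefault(pid, []).append(v)
    if keep_draws:
        draws = {pid: np.asarray(v) for pid, v in draws.items()}
    return PSASampleSet(n=n, seed=seed, wtp=config.wtp, d_cost=d_cost,
                        d_ly=d_ly, d_qaly=d_qaly, draws=draws)


def ceac(samples: PSASampleSet, wtp_grid) -> np.ndarray:
    """P(apixaban optimal) per WTP: share of draws with positive net benefit
    at that threshold (ties count half)."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty WTP grid")
    out = np.empty(wtp_grid.shape)
    for i, w in enumerate(wtp_grid):
        nb = w * samples.d_qaly - samples.d_cost
        out[i] = np.mean((nb > 0) + 0.5 * (nb == 0))
    return out
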