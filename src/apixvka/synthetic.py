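"""Synthetic inputs and independent oracles for testing the pipeline.

Nothing here is downloaded: the life table is a Gompertz stand-in
calibrated to Spain-like period life expectancy, random parameter packs
reuse the PSA sampling machinery, and two oracles cross-check the cohort
engine — an individual-level microsimulation driven by the same transition
rows (checks propagation and accrual) and a naive, fully independent
transition-matrix builder written with scalar arithmetic (checks the rate
math itself, intended for reduced two-event configurations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import compile_arm, initial_occupancy
from .outcomes import (_short_term_probs, baseline_utility, discount_factor,
                       regimen_cost_per_cycle, state_utility)
from .parameters import (EVENTS, LONG_TERM_EVENTS, SHORT_TERM_EVENTS,
                         LifeTable, ModelConfig)
from .states import enumerate_states
from .uncertainty import draw_psa_config

_LT = list(LONG_TERM_EVENTS)
_ST = list(SHORT_TERM_EVENTS)


# ---------------------------------------------------------------------------
# Synthetic life table
# ---------------------------------------------------------------------------

@dataclass
class GompertzSpec:
    """Gompertz mortality: hazard a * exp(b * age).

    The default slope is the textbook value for modern low-mortality
    populations (b = 0.11, matching Spain-2019-like old-age mortality,
    q90 ~ 0.13) and the level is calibrated by numerical search so that
    period life expectancy at birth is ~83 years; the resulting e70 ~ 16.4
    matches the 71%-male-weighted Spanish value.  Used as the synthetic
    stand-in for the national life table.
    """

    a: float = 6.5510e-06
    b: float = 0.11
    terminal_age: int = 100

    def validate(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Gompertz parameters must be positive")


def gompertz_life_table(spec: GompertzSpec | None = None) -> LifeTable:
    """Annual death probabilities qx(age) = 1 - exp(-H(age, age+1))."""
    spec = spec or GompertzSpec()
    spec.validate()
    ages = np.arange(0, spec.terminal_age + 1)
    qx = 1.0 - np.exp(-(spec.a / spec.b) * np.exp(spec.b * ages)
                      * (np.exp(spec.b) - 1.0))
    qx[-1] = 1.0
    lt = LifeTable(ages=ages, qx=qx, terminal_age=spec.terminal_age)
    lt.validate()
    return lt


def write_life_table_csv(life_table: LifeTable, path) -> None:
    import pandas as pd
    pd.DataFrame({"age": life_table.ages, "qx": life_table.qx}).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# Random and degenerate configurations
# ---------------------------------------------------------------------------

def random_config(rng: np.random.Generator, base: ModelConfig) -> ModelConfig:
    """A random valid parameter pack: every PSA-flagged input perturbed by
    its PSA distribution.  Used for property-based testing."""
    cfg, _ = draw_psa_config(base, rng)
    cfg.validate()
    return cfg


def equal_arm_config(config: ModelConfig) -> ModelConfig:
    """Make the VKA arm clinically and economically identical to apixaban
    (rates, P2Y12 mix, OAC price, discontinuation; monitoring zeroed) so
    that every increment must vanish exactly."""
    cfg = config.copy()
    for phase in ("triple_or_dual", "triple", "dual", "mono"):
        cfg.rates.rates[(phase, "vka")] = dict(cfg.rates.rates[(phase, "apixaban")])
        cfg.rates.ses[(phase, "vka")] = dict(cfg.rates.ses[(phase, "apixaban")])
    cfg.costs.p2y12_shares["vka"] = dict(cfg.costs.p2y12_shares["apixaban"])
    cfg.costs.drugs[cfg.vka_agent] = dict(cfg.costs.drugs["apixaban"])
    cfg.discontinuation.per_cycle_unrelated["vka"] = (
        cfg.discontinuation.per_cycle_unrelated["apixaban"])
    cfg.inr_tests_per_cycle = 0.0
    return cfg


# ---------------------------------------------------------------------------
# Individual-level microsimulation oracle
# ---------------------------------------------------------------------------

@dataclass
class MicrosimResults:
    n: int
    ly: float
    ly_se: float
    qaly: float
    qaly_se: float
    cost: float
    cost_se: float
    occupancy: np.ndarray      # (H+1, n_states) empirical state shares


def microsim_oracle(config: ModelConfig, arm: str, n_individuals: int,
                    seed: int, schedule=None, horizon: int | None = None
                    ) -> MicrosimResults:
    """Monte-Carlo estimate of the cohort outputs by simulating individuals
    through the same per-cycle transition rows.

    Per-individual discounted LY/QALY/cost are accrued along the sampled
    path; state-conditional expectations (incident-event and short-term
    costs and disutilities) are charged deterministically given the state,
    which leaves the estimator unbiased while shrinking its variance.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if schedule is None:
        from .scenarios import ScenarioSpec, build_schedule
        horizon_eff = horizon or config.horizon
        schedule = build_schedule(ScenarioSpec(), horizon_eff)
    c = compile_arm(config, arm, schedule, horizon=horizon)
    space = c.space
    H, nstates = c.horizon, space.n
    rng = np.random.default_rng(seed)

    disc = discount_factor(np.arange(H), config.discount_rate_annual,
                           config.cycle_length_years)
    t_years = config.cycle_length_years

    # per-(cycle, state) utility including intensity-weighted short-term
    # decrements, and per-(cycle, state) state-conditional costs
    base_u = baseline_utility(c.ages, config.cohort.male_share,
                              config.utilities.baseline_coeffs)
    ratio_s = np.array([state_utility(s, 0.0, config) for s in
                        space.states[:space.n_alive]])
    ratio_s /= baseline_utility(0.0, config.cohort.male_share,
                                config.utilities.baseline_coeffs)
    st_ratios = np.array([config.utilities.acute_ratio[e] for e in _ST])
    stf = np.prod(1.0 - c.p_st * (1.0 - st_ratios[None, None, :]), axis=2)

    u_val = np.zeros((H, nstates))
    cost_val = np.zeros((H, nstates))
    months = 12.0 * config.cycle_length_years
    drug_cost = np.array([regimen_cost_per_cycle(config, arm, ph)
                          for ph in c.phases])
    monitor = (config.inr_tests_per_cycle * config.costs.inr_cost_per_test
               if arm == "vka" else 0.0)
    acute_lt = np.array([config.costs.acute[e] for e in _LT])
    acute_st = np.array([config.costs.acute[e] for e in _ST])
    societal = config.perspective == "societal"
    soc_lt = np.array([config.costs.societal_acute.get(e, 0.0) for e in _LT])
    soc_st = np.array([config.costs.societal_acute.get(e, 0.0) for e in _ST])

    for i, s in enumerate(space.states[:space.n_alive]):
        tx = 0 if s.on_treatment else 1
        u_val[:, i] = base_u * ratio_s[i] * stf[:, tx]
        on_and_paying = s.on_treatment and s.phase != "acute"
        if on_and_paying:
            cost_val[:, i] += drug_cost + monitor
        if s.phase in ("post_acute", "acute"):
            maint = sum(config.costs.maintenance_monthly.get(e, 0.0)
                        for e in s.history) * months
            cost_val[:, i] += maint
            if societal:
                cost_val[:, i] += sum(
                    config.costs.societal_monthly.get(e, 0.0)
                    for e in s.history) * months
        # expected incident-event cost conditional on occupying this state
        ev_cost = c.p_event_eff[:, i, :] @ acute_lt
        st_cost = (1.0 - c.p_bg[:, i])[:, None] * c.p_st[:, tx, :] @ acute_st
        cost_val[:, i] += ev_cost + st_cost
        if societal:
            cost_val[:, i] += (c.p_event_eff[:, i, :] @ soc_lt
                               + (1.0 - c.p_bg[:, i])[:, None]
                               * c.p_st[:, tx, :] @ soc_st)

    cumP = np.cumsum(c.P, axis=2)

    occ0 = initial_occupancy(config, space)
    states = rng.choice(nstates, size=n_individuals, p=occ0)
    ly_i = np.zeros(n_individuals)
    qaly_i = np.zeros(n_individuals)
    cost_i = np.zeros(n_individuals)
    occupancy = np.zeros((H + 1, nstates))

    for t in range(H):
        np.add.at(occupancy[t], states, 1.0)
        alive = states != space.dead
        ly_i += disc[t] * t_years * alive
        qaly_i += disc[t] * t_years * u_val[t, states]
        cost_i += disc[t] * cost_val[t, states]
        rows = cumP[t, states, :]
        u = rng.random(n_individuals)
        states = (u[:, None] > rows).sum(axis=1)
    np.add.at(occupancy[H], states, 1.0)
    occupancy /= n_individuals

    def _mse(x):
        return float(x.mean()), float(x.std(ddof=1) / math.sqrt(n_individuals))

    ly, ly_se = _mse(ly_i)
    qaly, qaly_se = _mse(qaly_i)
    cost, cost_se = _mse(cost_i)
    return MicrosimResults(n=n_individuals, ly=ly, ly_se=ly_se, qaly=qaly,
                           qaly_se=qaly_se, cost=cost, cost_se=cost_se,
                           occupancy=occupancy)


# ---------------------------------------------------------------------------
# Independent brute-force transition builder
# ---------------------------------------------------------------------------

def naive_transition_matrix(config: ModelConfig, arm: str, schedule,
                            cycle: int) -> np.ndarray:
    """A from-scratch transition matrix built with scalar arithmetic only.

    Deliberately shares no probability code with the engine; meant to be
    compared on reduced configurations (e.g. only IS and ICH rates
    non-zero) as an independent check of the rate-to-probability math.
    """
    space = enumerate_states()
    n = space.n
    P = np.zeros((n, n))
    age = config.cohort.start_age + config.cycle_length_years * cycle
    ref_age = config.cohort.start_age + 0.5
    t = config.cycle_length_years
    phase = schedule.phase_at(cycle)
    qx = float(config.life_table.qx_at(age)[0])

    for i, s in enumerate(space.states):
        if s.phase == "dead":
            P[i, i] = 1.0
            continue
        # background death with the state's excess-mortality HR
        hr_mort = 1.0
        if not s.history:
            hr_mort = config.hrs.postacute_mortality["event_free"]
        else:
            for e in s.history:
                hr_mort *= config.hrs.postacute_mortality.get(
                    e, config.hrs.postacute_mortality["event_free"])
        p_bg = 1.0 - (1.0 - qx) ** (t * hr_mort)

        # competing long-term event hazards
        allowed = s.history if len(set(s.history)) == 2 else _LT
        rates = {}
        for e in allowed:
            if s.on_treatment:
                r = config.rates.rates[(phase, arm)][e]
            else:
                r = (config.rates.rates[("mono", "apixaban")][e]
                     / config.hrs.no_treatment[e])
            if age > ref_age and e in config.hrs.aging_per_decade:
                r *= config.hrs.aging_per_decade[e] ** ((age - ref_age) / 10.0)
            for prior in s.history:
                r *= config.hrs.subsequent[prior][e]
            rates[e] = r / 100.0
        lam = sum(rates.values())
        q_any = 1.0 - math.exp(-lam * t) if lam > 0 else 0.0

        from .states import HealthState
        death = p_bg
        for e, r in rates.items():
            if r == 0.0:
                continue
            p_e = r / lam * q_any * (1.0 - p_bg)
            cfr = config.fatality.cfr(e, age)
            death += p_e * cfr
            arrive = p_e * (1.0 - cfr)
            hist = tuple(sorted(set(s.history + (e,)),
                                key=_LT.index))
            dest_on = HealthState(history=hist, phase="acute", acute_event=e,
                                  on_treatment=True)
            dest_off = HealthState(history=hist, phase="acute", acute_event=e,
                                   on_treatment=False)
            d_e = config.discontinuation.per_event.get(e, 0.0)
            if s.on_treatment:
                P[i, space.index[dest_on]] += arrive * (1.0 - d_e)
                P[i, space.index[dest_off]] += arrive * d_e
            else:
                P[i, space.index[dest_off]] += arrive

        stay = (1.0 - q_any) * (1.0 - p_bg)
        next_phase = "post_acute" if s.phase == "acute" else s.phase
        hist = s.history
        prog_on = HealthState(history=hist, phase=next_phase, on_treatment=True)
        prog_off = HealthState(history=hist, phase=next_phase,
                               on_treatment=False)
        if s.on_treatment:
            d_u = config.discontinuation.per_cycle_unrelated[arm]
            P[i, space.index[prog_on]] += stay * (1.0 - d_u)
            P[i, space.index[prog_off]] += stay * d_u
        else:
            P[i, space.index[prog_off]] += stay
        P[i, space.dead] += death
    return P


def reduced_two_event_config(config: ModelConfig) -> ModelConfig:
    """Zero out MI/OMB and short-term rates, leaving an IS/ICH-only model."""
    cfg = config.copy()
    for key in list(cfg.rates.rates):
        for e in ("MI", "OMB") + tuple(_ST):
            cfg.rates.rates[key][e] = 0.0
    return cfg
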