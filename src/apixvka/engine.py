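"""Per-cycle transition probabilities and cohort propagation.

The builder combines, for every alive state and cycle:

1. phase-specific event rates (trial rates while on triple/dual therapy,
   long-term monotherapy rates afterwards, no-treatment rates once off),
   scaled by aging and event-history hazard multipliers and converted to
   competing-risk probabilities over the allowed long-term events,
2. the acute-cycle case fatality of each incident event,
3. background mortality from the life table with the state's excess
   mortality HR applied on the hazard scale, pro-rated to the cycle,
4. acute -> post-acute progression after exactly one cycle,
5. treatment discontinuation: event-related (resolved in the acute cycle
   among survivors) and a per-cycle probability unrelated to events.

Background death acts first as an independent cause each cycle; among its
survivors events compete and case fatality splits each incident event into
death vs arrival in the acute state.  Every row therefore sums to one by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (ARMS, EVENTS, LONG_TERM_EVENTS, SHORT_TERM_EVENTS,
                         ModelConfig, derive_no_treatment_rates)
from .states import StateSpace, enumerate_states

_LT = list(LONG_TERM_EVENTS)
_ST = list(SHORT_TERM_EVENTS)


def rate_to_competing_probs(rates, cycle_length_years: float):
    """Convert competing event rates (per 100 patient-years) to per-cycle
    probabilities.

    p_i = (r_i / sum r) * (1 - exp(-sum r * t)) with rates per person-year;
    the remainder is the stay probability.
    """
    r = np.asarray(rates, dtype=float) / 100.0
    if np.any(r < 0):
        raise ValueError("negative event rate")
    total = r.sum()
    if total <= 0:
        return np.zeros_like(r), 1.0
    q = 1.0 - np.exp(-total * cycle_length_years)
    p = r / total * q
    return p, 1.0 - p.sum()


def aging_multiplier(event: str, age_now: float, reference_age: float,
                     hrs) -> float:
    """Hazard multiplier for aging: HR_decade^((age - ref)/10), with no
    adjustment during the first 6 months (trial-covered period)."""
    hr = hrs.aging_per_decade.get(event)
    if hr is None:
        return 1.0
    expo = max(age_now - reference_age, 0.0) / 10.0
    return float(hr ** expo)


def history_multiplier(history, future_event: str, hrs,
                       combination: str = "product") -> float:
    """Product (or max) of prior-event -> future-event hazard ratios."""
    from .states import allowed_future_events
    if future_event not in allowed_future_events(tuple(history)):
        raise ValueError(
            f"event {future_event} not allowed with history {tuple(history)}")
    vals = [hrs.subsequent[prior][future_event] for prior in history]
    if not vals:
        return 1.0
    return float(np.prod(vals)) if combination == "product" else float(max(vals))


def event_fatality(event: str, age: float, fatality) -> float:
    """Probability of death in the acute cycle of a long-term event."""
    return fatality.cfr(event, age)


def background_death_prob(age_or_qx, state_hr: float, life_table=None) -> float:
    """Per-cycle background death probability: 1 - (1-qx)^(0.25 * HR)."""
    qx = (life_table.qx_at(age_or_qx)[0] if life_table is not None
          else float(age_or_qx))
    if not 0.0 <= qx <= 1.0:
        raise ValueError("qx out of [0,1]")
    if state_hr <= 0:
        raise ValueError("state mortality HR must be > 0")
    if qx >= 1.0:
        return 1.0
    return 1.0 - (1.0 - qx) ** (0.25 * state_hr)


@dataclass
class CompiledArm:
    """All cycle-indexed quantities for one arm under one schedule."""

    arm: str
    horizon: int
    ages: np.ndarray           # (H,) cohort age at the start of each cycle
    phases: list               # phase label per cycle
    P: np.ndarray              # (H, n, n) transition matrices
    p_event_eff: np.ndarray    # (H, n_alive, 4) incident long-term event probs
    p_st: np.ndarray           # (H, 2, 3) short-term probs by tx (on=0, off=1)
    p_bg: np.ndarray           # (H, n_alive) background death probability
    space: StateSpace


def compile_arm(config: ModelConfig, arm: str, schedule,
                horizon: int | None = None,
                space: StateSpace | None = None) -> CompiledArm:
    """Vectorized construction of every cycle's transition matrix."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm}")
    space = space or enumerate_states()
    H = horizon if horizon is not None else config.horizon
    na = space.n_alive
    t_years = config.cycle_length_years

    ages = config.cohort.start_age + t_years * np.arange(H)
    phases = schedule.phases(H)

    # per-cycle on-treatment base rates (H, 7) and static off rates (7,)
    on_rates = np.array([[config.rates.rates[(phases[t], arm)][e]
                          for e in EVENTS] for t in range(H)])
    off_all = derive_no_treatment_rates(
        config.rates.rates[("mono", "apixaban")], config.hrs.no_treatment)
    off_rates = np.array([off_all[e] for e in EVENTS])

    # aging multipliers (H, 4): none during the trial-covered first 6 months
    ref_age = config.cohort.start_age + 0.5
    expo = np.maximum(ages - ref_age, 0.0)[:, None] / 10.0
    aging_hr = np.array([config.hrs.aging_per_decade[e] for e in _LT])
    aging = aging_hr[None, :] ** expo                        # (H, 4)

    hist_mult = space.history_multipliers(config.hrs,
                                          config.joint_hr_combination)
    mort_hr = space.mortality_hrs(config.hrs)

    lt_cols = [EVENTS.index(e) for e in _LT]
    st_cols = [EVENTS.index(e) for e in _ST]

    # long-term rates per (cycle, state, event)
    base_on = on_rates[:, lt_cols] * aging                   # (H, 4)
    base_off = off_rates[lt_cols][None, :] * aging           # (H, 4)
    R = np.where(space.on_mask[None, :, None], base_on[:, None, :],
                 base_off[:, None, :])
    R = R * hist_mult[None, :, :] * space.allowed[None, :, :]

    lam = R.sum(axis=2) / 100.0                              # (H, na) per year
    q = 1.0 - np.exp(-lam * t_years)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(lam[..., None] > 0, R / R.sum(axis=2, keepdims=True),
                         0.0)
    p_ev = share * q[..., None]                              # (H, na, 4)

    # short-term intensities depend on treatment status only (no aging or
    # history effect is reported for them)
    p_st = np.empty((H, 2, 3))
    p_st[:, 0, :] = 1.0 - np.exp(-on_rates[:, st_cols] / 100.0 * t_years)
    p_st[:, 1, :] = 1.0 - np.exp(-off_rates[st_cols][None, :] / 100.0 * t_years)

    # case fatality by event at each cycle's age
    cfr = np.stack([config.fatality.cfr_vector(e, ages) for e in _LT], axis=1)

    # background mortality with the state's excess-mortality HR
    qx = config.life_table.qx_at(ages)                       # (H,)
    p_bg = 1.0 - (1.0 - qx[:, None]) ** (t_years * mort_hr[None, :])

    d_event = np.array([config.discontinuation.per_event.get(e, 0.0)
                        for e in _LT])
    d_unrel = config.discontinuation.per_cycle_unrelated[arm]

    surv = 1.0 - p_bg                                        # (H, na)
    ev_death = (p_ev * cfr[:, None, :]).sum(axis=2)          # (H, na)
    dead_col = p_bg + surv * ev_death
    ev_arrive = p_ev * (1.0 - cfr[:, None, :]) * surv[..., None]
    stay = (1.0 - p_ev.sum(axis=2)) * surv                   # (H, na)

    on = space.on_mask
    w_on_dest = np.where(on[:, None], 1.0 - d_event[None, :], 0.0)
    w_off_dest = np.where(on[:, None], d_event[None, :], 1.0)
    w_stay_on = np.where(on, 1.0 - d_unrel, 0.0)
    w_stay_off = np.where(on, d_unrel, 1.0)

    P = np.zeros((H, space.n, space.n))
    src = np.arange(na)
    for j in range(len(_LT)):
        P[:, src, space.dest_on[:, j]] += ev_arrive[:, :, j] * w_on_dest[:, j]
        P[:, src, space.dest_off[:, j]] += ev_arrive[:, :, j] * w_off_dest[:, j]
    P[:, src, space.prog_on] += stay * w_stay_on[None, :]
    P[:, src, space.prog_off] += stay * w_stay_off[None, :]
    P[:, src, space.dead] += dead_col
    P[:, space.dead, space.dead] = 1.0

    row_sums = P.sum(axis=2)
    if not np.allclose(row_sums, 1.0, atol=1e-12):
        worst = float(np.abs(row_sums - 1.0).max())
        raise FloatingPointError(
            f"transition rows fail to normalize (max |sum-1| = {worst:g})")

    return CompiledArm(arm=arm, horizon=H, ages=ages, phases=phases, P=P,
                       p_event_eff=p_ev * surv[..., None], p_st=p_st,
                       p_bg=p_bg, space=space)


def build_transition_row(state, cycle: int, schedule, config: ModelConfig,
                         arm: str = "apixaban", compiled: CompiledArm = None):
    """One origin state's destination probabilities at one cycle, plus the
    short-term event intensities that apply to it."""
    c = compiled or compile_arm(config, arm, schedule)
    space = c.space
    i = space.index[state]
    row = c.P[cycle, i, :]
    if state.phase == "dead":
        return row, np.zeros(3)
    tx = 0 if state.on_treatment else 1
    return row, c.p_st[cycle, tx, :]


@dataclass
class CohortTrace:
    """Cycle-by-cycle cohort occupancy and incident-event channels."""

    occupancy: np.ndarray      # (H+1, n) state shares; row 0 is the initial split
    incident_lt: np.ndarray    # (H, 4) incident long-term events per cycle
    incident_st: np.ndarray    # (H, 3) short-term event intensities per cycle
    ages: np.ndarray           # (H,)
    phases: list
    space: StateSpace
    arm: str

    @property
    def horizon(self) -> int:
        return len(self.ages)

    def alive(self) -> np.ndarray:
        """Alive share at the start of each accrual cycle (length H)."""
        return 1.0 - self.occupancy[:-1, self.space.dead]

    def on_treatment_share(self) -> np.ndarray:
        occ = self.occupancy[:-1, :self.space.n_alive]
        return occ[:, self.space.on_mask].sum(axis=1)

    def to_frame(self):
        import pandas as pd
        cols = [s.label() for s in self.space.states]
        df = pd.DataFrame(self.occupancy, columns=cols)
        df.index.name = "cycle"
        return df

    def events_frame(self):
        import pandas as pd
        df = pd.DataFrame(np.hstack([self.incident_lt, self.incident_st]),
                          columns=_LT + _ST)
        df.index.name = "cycle"
        return df


def initial_occupancy(config: ModelConfig, space: StateSpace) -> np.ndarray:
    """Cycle-0 split: a post-acute-MI share (recent ACS) and the remainder
    event-free, everyone on treatment."""
    occ0 = np.zeros(space.n)
    from .states import HealthState
    post_mi = HealthState(history=("MI",), phase="post_acute", on_treatment=True)
    free = HealthState(phase="event_free", on_treatment=True)
    s = config.cohort.initial_postacute_mi_share
    occ0[space.index[post_mi]] = s
    occ0[space.index[free]] = 1.0 - s
    return occ0


def run_trace(config: ModelConfig, arm: str, schedule,
              horizon: int | None = None, space: StateSpace | None = None,
              compiled: CompiledArm | None = None) -> CohortTrace:
    """Propagate the cohort through every cycle of the horizon."""
    c = compiled or compile_arm(config, arm, schedule, horizon=horizon,
                                space=space)
    space = c.space
    H = c.horizon
    occ = np.empty((H + 1, space.n))
    occ[0] = initial_occupancy(config, space)
    inc_lt = np.empty((H, 4))
    inc_st = np.empty((H, 3))
    on = space.on_mask
    for t in range(H):
        row = occ[t, :space.n_alive]
        inc_lt[t] = row @ c.p_event_eff[t]
        survivors = row * (1.0 - c.p_bg[t])
        inc_st[t] = (survivors[on].sum() * c.p_st[t, 0, :]
                     + survivors[~on].sum() * c.p_st[t, 1, :])
        occ[t + 1] = occ[t] @ c.P[t]

    sums = occ.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-10):
        raise FloatingPointError("trace occupancy rows fail to sum to 1")
    return CohortTrace(occupancy=occ, incident_lt=inc_lt, incident_st=inc_st,
                       ages=c.ages, phases=c.phases, space=space, arm=arm)
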