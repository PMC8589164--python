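"""Discounted costs, life years, QALYs and incremental cost-effectiveness.

Costs and health outcomes are accrued at cycle start (no half-cycle
correction by default) and discounted at the annual rate pro-rated to the
3-month cycle.  Event counts are reported undiscounted per 100 patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CohortTrace
from .parameters import (EVENTS, LONG_TERM_EVENTS, SHORT_TERM_EVENTS,
                         ModelConfig, baseline_utility,
                         derive_no_treatment_rates, weighted_p2y12_cost)

_LT = list(LONG_TERM_EVENTS)
_ST = list(SHORT_TERM_EVENTS)

BLEEDING_EVENTS = ("ICH", "OMB", "CRNMB")
ISCHEMIC_EVENTS = ("MI", "IS", "REV", "SE")


def discount_factor(cycle, annual_rate: float,
                    cycle_length_years: float = 0.25):
    """(1 + r)^(-cycle * cycle_length); cycle 0 discounts to 1."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    cycle = np.asarray(cycle, dtype=float)
    return (1.0 + annual_rate) ** (-cycle * cycle_length_years)


def state_utility(state, age: float, config: ModelConfig,
                  short_term_intensities=None) -> float:
    """Per-cycle utility weight of one state at one age.

    Baseline general-population utility times the acute ratio of the
    incident event (if any), times the post-acute ratios of prior history
    events, times intensity-weighted short-term event ratios.  Dead is 0.
    """
    if state.phase == "dead":
        return 0.0
    u = baseline_utility(age, config.cohort.male_share,
                         config.utilities.baseline_coeffs)
    if state.phase == "acute":
        u *= config.utilities.acute_ratio[state.acute_event]
        for e in state.history:
            if e != state.acute_event:
                u *= config.utilities.post_ratio[e]
    elif state.phase == "post_acute":
        for e in state.history:
            u *= config.utilities.post_ratio[e]
    if short_term_intensities is not None:
        for ev, p in zip(_ST, short_term_intensities):
            u *= 1.0 - p * (1.0 - config.utilities.acute_ratio[ev])
    return u


@dataclass
class ArmResults:
    """Discounted per-patient totals for one arm (euros, years)."""

    arm: str
    treatment_cost: float
    monitoring_cost: float
    acute_event_cost: float
    maintenance_cost: float
    indirect_acute_cost: float
    indirect_maintenance_cost: float
    ly: float
    qaly: float
    events_per_100: dict
    time_on_treatment: float
    time_off_treatment: float
    perspective: str = "payer"

    @property
    def clinical_event_cost(self) -> float:
        return self.acute_event_cost + self.maintenance_cost

    @property
    def total_cost_payer(self) -> float:
        return (self.treatment_cost + self.monitoring_cost
                + self.acute_event_cost + self.maintenance_cost)

    @property
    def total_cost_societal(self) -> float:
        return (self.total_cost_payer + self.indirect_acute_cost
                + self.indirect_maintenance_cost)

    @property
    def total_cost(self) -> float:
        return (self.total_cost_societal if self.perspective == "societal"
                else self.total_cost_payer)

    def bleeding_per_100(self) -> float:
        return sum(self.events_per_100[e] for e in BLEEDING_EVENTS)

    def ischemic_per_100(self) -> float:
        return sum(self.events_per_100[e] for e in ISCHEMIC_EVENTS)

    def to_dict(self) -> dict:
        d = {
            "arm": self.arm,
            "treatment_cost": round(self.treatment_cost, 2),
            "monitoring_cost": round(self.monitoring_cost, 2),
            "acute_cost": round(self.acute_event_cost, 2),
            "post_acute_cost": round(self.maintenance_cost, 2),
            "total_cost_payer": round(self.total_cost_payer, 2),
            "indirect_acute_cost": round(self.indirect_acute_cost, 2),
            "indirect_post_acute_cost": round(self.indirect_maintenance_cost, 2),
            "total_cost_societal": round(self.total_cost_societal, 2),
            "total_ly": round(self.ly, 2),
            "total_qaly": round(self.qaly, 2),
            "time_on_treatment_years": round(self.time_on_treatment, 2),
            "time_off_treatment_years": round(self.time_off_treatment, 2),
            "bleeding_per_100": round(self.bleeding_per_100(), 1),
            "ischemic_per_100": round(self.ischemic_per_100(), 1),
        }
        for ev in EVENTS:
            d[f"events_per_100.{ev}"] = round(self.events_per_100[ev], 1)
        return d


@dataclass
class IncrementalResults:
    """Apixaban-minus-VKA differences and decision measures."""

    d_cost: float
    d_ly: float
    d_qaly: float
    icer: float                # €/QALY; +/-inf when d_qaly == 0
    inmb: float                # wtp * dQALY - dCost
    inhb: float                # inmb / wtp, in QALYs
    dominance: str             # dominant | cost_effective | not_cost_effective
                               # | dominated | sw_tradeoff
    wtp: float
    perspective: str = "payer"

    def to_dict(self) -> dict:
        return {
            "d_cost": round(self.d_cost, 2), "d_ly": round(self.d_ly, 4),
            "d_qaly": round(self.d_qaly, 4),
            "icer": (None if not np.isfinite(self.icer)
                     else round(self.icer, 2)),
            "inmb": round(self.inmb, 2), "inhb": round(self.inhb, 4),
            "dominance": self.dominance, "wtp": self.wtp,
            "perspective": self.perspective,
        }


def _short_term_probs(config: ModelConfig, arm: str, phases) -> np.ndarray:
    """(H, 2, 3) per-cycle short-term event probabilities by tx status."""
    t_years = config.cycle_length_years
    off_all = derive_no_treatment_rates(
        config.rates.rates[("mono", "apixaban")], config.hrs.no_treatment)
    on = np.array([[config.rates.rates[(ph, arm)][e] for e in _ST]
                   for ph in phases])
    off = np.array([off_all[e] for e in _ST])
    out = np.empty((len(phases), 2, 3))
    out[:, 0, :] = 1.0 - np.exp(-on / 100.0 * t_years)
    out[:, 1, :] = 1.0 - np.exp(-off[None, :] / 100.0 * t_years)
    return out


def regimen_cost_per_cycle(config: ModelConfig, arm: str, phase: str) -> float:
    """On-treatment drug cost of one cycle in a given phase."""
    drugs = config.costs.drugs
    per_cycle = {a: d["cost_per_cycle"] for a, d in drugs.items()}
    oac = (per_cycle["apixaban"] if arm == "apixaban"
           else per_cycle[config.vka_agent])
    p2y12 = weighted_p2y12_cost(config.costs.p2y12_shares[arm], per_cycle)
    aspirin = per_cycle["aspirin"]
    if phase == "mono":
        return oac
    if phase == "dual":
        return oac + p2y12
    if phase == "triple":
        return oac + p2y12 + aspirin
    if phase == "triple_or_dual":
        return oac + p2y12 + config.triple_share_in_blend * aspirin
    raise ValueError(f"unknown phase {phase}")


def cycle_costs(trace: CohortTrace, cycle: int, config: ModelConfig,
                perspective: str | None = None) -> dict:
    """Discounted cost components accrued in one cycle (see summarize)."""
    comp = _cost_components(trace, config)
    out = {k: float(v[cycle]) for k, v in comp.items()}
    persp = perspective or config.perspective
    if persp not in ("payer", "societal"):
        raise ValueError(f"unknown perspective {persp}")
    if persp == "payer":
        out["indirect_acute"] = 0.0
        out["indirect_maintenance"] = 0.0
    return out


def _cost_components(trace: CohortTrace, config: ModelConfig) -> dict:
    """Per-cycle discounted cost component vectors for a whole trace."""
    space = trace.space
    H = trace.horizon
    occ = trace.occupancy
    occ_alive = occ[:-1, :space.n_alive]
    if config.half_cycle_correction:
        occ_alive = 0.5 * (occ[:-1, :space.n_alive] + occ[1:, :space.n_alive])
    disc = discount_factor(np.arange(H), config.discount_rate_annual,
                           config.cycle_length_years)

    on_occ = occ_alive[:, space.on_mask].sum(axis=1)
    # treatment interruption after an event: the on-treatment occupancy of
    # acute states entered in the last `interruption_cycles` cycles pays no
    # drug (or monitoring) cost; acute states always hold the just-incident
    on_acute = occ_alive[:, space.on_mask & space.is_acute].sum(axis=1)
    k = config.discontinuation.interruption_cycles
    interrupted = np.zeros(H)
    for lag in range(k):
        interrupted[lag:] += on_acute[:H - lag] if lag else on_acute
    interrupted = np.minimum(interrupted, on_occ)
    paying = on_occ - interrupted

    drug_cost = np.array([regimen_cost_per_cycle(config, trace.arm, ph)
                          for ph in trace.phases])
    treatment = paying * drug_cost * disc

    monitoring = np.zeros(H)
    if trace.arm == "vka":
        monitoring = (paying * config.inr_tests_per_cycle
                      * config.costs.inr_cost_per_test * disc)

    acute_cost_lt = np.array([config.costs.acute[e] for e in _LT])
    acute_cost_st = np.array([config.costs.acute[e] for e in _ST])
    acute = (trace.incident_lt @ acute_cost_lt
             + trace.incident_st @ acute_cost_st) * disc

    # maintenance accrues from the event cycle onwards: acute states already
    # carry the maintenance of every event in their history (including the
    # incident one), post-acute states likewise
    months = 12.0 * config.cycle_length_years
    maint_per_state = np.zeros(space.n_alive)
    soc_per_state = np.zeros(space.n_alive)
    for i in range(space.n_alive):
        if space.is_post[i] or space.is_acute[i]:
            for j, e in enumerate(_LT):
                if space.hist_mask[i, j]:
                    maint_per_state[i] += months * config.costs.maintenance_monthly.get(e, 0.0)
                    soc_per_state[i] += months * config.costs.societal_monthly.get(e, 0.0)
    maintenance = occ_alive @ maint_per_state * disc
    indirect_maintenance = occ_alive @ soc_per_state * disc

    soc_acute_lt = np.array([config.costs.societal_acute.get(e, 0.0)
                             for e in _LT])
    soc_acute_st = np.array([config.costs.societal_acute.get(e, 0.0)
                             for e in _ST])
    indirect_acute = (trace.incident_lt @ soc_acute_lt
                      + trace.incident_st @ soc_acute_st) * disc

    return {"treatment": treatment, "monitoring": monitoring, "acute": acute,
            "maintenance": maintenance, "indirect_acute": indirect_acute,
            "indirect_maintenance": indirect_maintenance}


def summarize(trace: CohortTrace, config: ModelConfig) -> ArmResults:
    """Reduce a cohort trace to discounted totals and event counts."""
    space = trace.space
    H = trace.horizon
    occ = trace.occupancy
    occ_alive = occ[:-1, :space.n_alive]
    if config.half_cycle_correction:
        occ_alive = 0.5 * (occ[:-1, :space.n_alive] + occ[1:, :space.n_alive])
    disc = discount_factor(np.arange(H), config.discount_rate_annual,
                           config.cycle_length_years)
    t_years = config.cycle_length_years

    alive = occ_alive.sum(axis=1)
    ly = float((disc * alive).sum() * t_years)

    base_u = baseline_utility(trace.ages, config.cohort.male_share,
                              config.utilities.baseline_coeffs)
    ratio_s = np.ones(space.n_alive)
    for i, s in enumerate(space.states[:space.n_alive]):
        ratio_s[i] = state_utility(s, 0.0, config) / baseline_utility(
            0.0, config.cohort.male_share, config.utilities.baseline_coeffs)
    p_st = _short_term_probs(config, trace.arm, trace.phases)
    st_ratios = np.array([config.utilities.acute_ratio[e] for e in _ST])
    stf = np.prod(1.0 - p_st * (1.0 - st_ratios[None, None, :]), axis=2)  # (H,2)
    on = space.on_mask
    util = base_u * (
        (occ_alive[:, on] * ratio_s[on]).sum(axis=1) * stf[:, 0]
        + (occ_alive[:, ~on] * ratio_s[~on]).sum(axis=1) * stf[:, 1])
    qaly = float((disc * util).sum() * t_years)

    comp = _cost_components(trace, config)

    events = {}
    for j, e in enumerate(_LT):
        events[e] = float(trace.incident_lt[:, j].sum() * 100.0)
    for j, e in enumerate(_ST):
        events[e] = float(trace.incident_st[:, j].sum() * 100.0)

    # discounted, so that time on + time off equals discounted LY
    on_time = float((disc * occ[:-1, :space.n_alive][:, on].sum(axis=1)).sum()
                    * t_years)
    off_time = float((disc * occ[:-1, :space.n_alive][:, ~on].sum(axis=1)).sum()
                     * t_years)

    return ArmResults(
        arm=trace.arm,
        treatment_cost=float(comp["treatment"].sum()),
        monitoring_cost=float(comp["monitoring"].sum()),
        acute_event_cost=float(comp["acute"].sum()),
        maintenance_cost=float(comp["maintenance"].sum()),
        indirect_acute_cost=float(comp["indirect_acute"].sum()),
        indirect_maintenance_cost=float(comp["indirect_maintenance"].sum()),
        ly=ly, qaly=qaly, events_per_100=events,
        time_on_treatment=on_time, time_off_treatment=off_time,
        perspective=config.perspective,
    )


def incremental(apixaban: ArmResults, vka: ArmResults, wtp: float,
                perspective: str | None = None) -> IncrementalResults:
    """Apixaban-vs-VKA increments, ICER, net benefit and dominance class."""
    persp = perspective or apixaban.perspective
    if persp == "societal":
        d_cost = apixaban.total_cost_societal - vka.total_cost_societal
    else:
        d_cost = apixaban.total_cost_payer - vka.total_cost_payer
    d_ly = apixaban.ly - vka.ly
    d_qaly = apixaban.qaly - vka.qaly
    if d_qaly == 0.0:
        icer = np.inf if d_cost > 0 else (-np.inf if d_cost < 0 else 0.0)
    else:
        icer = d_cost / d_qaly
    inmb = wtp * d_qaly - d_cost
    inhb = inmb / wtp
    if d_qaly > 0 and d_cost < 0:
        dom = "dominant"
    elif d_qaly >= 0 and d_cost >= 0:
        dom = "cost_effective" if inmb >= 0 else "not_cost_effective"
    elif d_qaly < 0 and d_cost > 0:
        dom = "dominated"
    elif d_qaly <= 0 and d_cost <= 0:
        dom = "sw_tradeoff"
    else:
        dom = "dominant"
    return IncrementalResults(d_cost=d_cost, d_ly=d_ly, d_qaly=d_qaly,
                              icer=float(icer), inmb=inmb, inhb=inhb,
                              dominance=dom, wtp=wtp, perspective=persp)
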