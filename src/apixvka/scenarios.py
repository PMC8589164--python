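"""Treatment-strategy schedules, the base case, and scenario runs.

Three step-down strategies are supported (months are converted to 3-month
cycles; no step-up is allowed):

* ``triple_or_dual_mono`` (base case): the blended triple-or-dual regimen
  for 6 months, then OAC monotherapy;
* ``triple_dual_mono``: triple for 3 months, dual until the monotherapy
  switch (6-9 months, default 9);
* ``dual_mono``: dual until the monotherapy switch (6-12 months,
  default 12).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .engine import run_trace
from .outcomes import ArmResults, IncrementalResults, incremental, summarize
from .parameters import ModelConfig, StrategySchedule

STRATEGIES = ("triple_or_dual_mono", "triple_dual_mono", "dual_mono")

_DEFAULT_SWITCH_MONTHS = {
    "triple_or_dual_mono": {"mono": 6},
    "triple_dual_mono": {"dual": 3, "mono": 9},
    "dual_mono": {"mono": 12},
}

MONTHS_PER_CYCLE = 3


@dataclass
class ScenarioSpec:
    """Overrides applied on top of the base configuration for one scenario."""

    name: str = "base"
    strategy: str = "triple_or_dual_mono"
    switch_months: dict = field(default_factory=dict)
    horizon_years: float | None = None          # None = lifetime
    perspective: str | None = None
    vka_agent: str | None = None                # acenocoumarol | warfarin
    discount_rate: float | None = None
    disc_event_override: dict | None = None     # e.g. alternative published
                                                # event-related discontinuation
    wtp: float | None = None


def _months_to_cycle(months: float) -> int:
    cycles = months / MONTHS_PER_CYCLE
    if cycles != int(cycles):
        raise ValueError(f"switch at {months} months is not on a cycle boundary")
    return int(cycles)


def build_schedule(spec: ScenarioSpec | str, horizon: int) -> StrategySchedule:
    """Cycle-indexed phase blocks for a strategy (step-down only)."""
    if isinstance(spec, str):
        spec = ScenarioSpec(strategy=spec)
    if spec.strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {spec.strategy}")
    switches = dict(_DEFAULT_SWITCH_MONTHS[spec.strategy])
    switches.update(spec.switch_months)
    mono_c = _months_to_cycle(switches["mono"])
    blocks = []
    if spec.strategy == "triple_or_dual_mono":
        blocks.append(("triple_or_dual", 0, mono_c))
    elif spec.strategy == "triple_dual_mono":
        dual_c = _months_to_cycle(switches["dual"])
        if not 0 < dual_c < mono_c:
            raise ValueError("switch timepoints must be increasing")
        blocks.append(("triple", 0, dual_c))
        blocks.append(("dual", dual_c, mono_c))
    else:  # dual_mono
        blocks.append(("dual", 0, mono_c))
    if mono_c <= 0 or mono_c >= horizon:
        raise ValueError("monotherapy switch must fall inside the horizon")
    blocks.append(("mono", mono_c, horizon))
    sched = StrategySchedule(blocks=blocks)
    sched.validate(horizon)
    return sched


@dataclass
class ComparisonResults:
    """Both arms plus the incremental comparison for one scenario."""

    name: str
    apixaban: ArmResults
    vka: ArmResults
    increment: IncrementalResults
    increment_societal: IncrementalResults


def apply_spec(config: ModelConfig, spec: ScenarioSpec) -> ModelConfig:
    """Return a copy of the config with the scenario overrides applied."""
    cfg = config.copy()
    if spec.perspective is not None:
        cfg.perspective = spec.perspective
    if spec.vka_agent is not None:
        cfg.vka_agent = spec.vka_agent
    if spec.discount_rate is not None:
        cfg.discount_rate_annual = spec.discount_rate
    if spec.wtp is not None:
        cfg.wtp = spec.wtp
    if spec.disc_event_override:
        cfg.discontinuation.per_event.update(spec.disc_event_override)
    cfg.validate()
    return cfg


def scenario_horizon(config: ModelConfig, spec: ScenarioSpec) -> int:
    if spec.horizon_years is None:
        return config.horizon
    cycles = math.ceil(spec.horizon_years / config.cycle_length_years)
    return min(cycles, config.horizon)


def run_scenario(config: ModelConfig, spec: ScenarioSpec | None = None
                 ) -> ComparisonResults:
    """Solve both arms under a scenario and compute the increments."""
    spec = spec or ScenarioSpec()
    cfg = apply_spec(config, spec)
    horizon = scenario_horizon(cfg, spec)
    schedule = build_schedule(spec, horizon)
    results = {}
    for arm in ("apixaban", "vka"):
        trace = run_trace(cfg, arm, schedule, horizon=horizon)
        results[arm] = summarize(trace, cfg)
    inc = incremental(results["apixaban"], results["vka"], cfg.wtp, "payer")
    inc_soc = incremental(results["apixaban"], results["vka"], cfg.wtp,
                          "societal")
    return ComparisonResults(name=spec.name, apixaban=results["apixaban"],
                             vka=results["vka"], increment=inc,
                             increment_societal=inc_soc)


def run_base_case(config: ModelConfig) -> ComparisonResults:
    """The base case: blended triple-or-dual for 6 months, then monotherapy."""
    return run_scenario(config, ScenarioSpec(name="base"))


def standard_scenarios() -> list[ScenarioSpec]:
    """The scenario grid exercised in the published analysis."""
    return [
        ScenarioSpec(name="base"),
        ScenarioSpec(name="warfarin_cost", vka_agent="warfarin"),
        ScenarioSpec(name="horizon_10y", horizon_years=10.0),
        ScenarioSpec(name="horizon_20y", horizon_years=20.0),
        ScenarioSpec(name="triple_dual_mono_12m", strategy="triple_dual_mono",
                     switch_months={"dual": 3, "mono": 12}),
        ScenarioSpec(name="triple_dual_mono_9m", strategy="triple_dual_mono"),
        ScenarioSpec(name="dual_mono_12m", strategy="dual_mono"),
        ScenarioSpec(name="dual_mono_6m", strategy="dual_mono",
                     switch_months={"mono": 6}),
        ScenarioSpec(name="societal", perspective="societal"),
    ]


def run_scenario_grid(config: ModelConfig,
                      specs: list[ScenarioSpec] | None = None) -> dict:
    specs = specs if specs is not None else standard_scenarios()
    return {s.name: run_scenario(config, s) for s in specs}
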