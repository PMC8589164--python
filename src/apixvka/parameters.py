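"""Typed, validated model parameters and their on-disk representation.

The model compares two oral-anticoagulation arms (apixaban vs VKA) in
atrial-fibrillation patients who recently had an acute coronary syndrome
and/or PCI.  Every input lives in a "parameter pack": a directory of YAML
and CSV files (one file per input block) shipped with the package and
overridable by the user.  Each scalar input carries a stable identifier
(e.g. ``rate.mono.apixaban.IS``) through which the deterministic and
probabilistic sensitivity analyses address it.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

# Canonical event ordering used throughout the package.
LONG_TERM_EVENTS = ("MI", "IS", "ICH", "OMB")
SHORT_TERM_EVENTS = ("CRNMB", "REV", "SE")
EVENTS = LONG_TERM_EVENTS + SHORT_TERM_EVENTS
ARMS = ("apixaban", "vka")
ON_TREATMENT_PHASES = ("triple_or_dual", "triple", "dual", "mono")
# Short-term events borrow the no-treatment HR of a clinically similar
# long-term event.
TIED_NO_TREATMENT_HR = {"CRNMB": "OMB", "REV": "MI", "SE": "IS"}

DAYS_PER_YEAR = 365.25


class ValidationError(ValueError):
    """A parameter violated one of its declared invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EventRateTable:
    """Event rates per 100 patient-years by treatment phase and arm.

    ``rates[(phase, arm)][event]`` and matching standard errors.  The
    triple/dual-phase rates come from the ACS/PCI trial population, the
    monotherapy rates from long-term anticoagulation follow-up.
    """

    rates: dict
    ses: dict

    def rate(self, phase: str, arm: str, event: str) -> float:
        return self.rates[(phase, arm)][event]

    def validate(self) -> None:
        for phase in ON_TREATMENT_PHASES:
            for arm in ARMS:
                key = (phase, arm)
                _require(key in self.rates, f"event rates missing block {key}")
                for ev in EVENTS:
                    _require(ev in self.rates[key],
                             f"event rate missing for {phase}/{arm}/{ev}")
                    r = self.rates[key][ev]
                    s = self.ses[key][ev]
                    _require(r >= 0, f"rate.{phase}.{arm}.{ev} negative: {r}")
                    _require(s >= 0, f"rate SE {phase}/{arm}/{ev} negative")


@dataclass
class HazardRatioSet:
    """Hazard ratios modifying the baseline event and death hazards.

    * ``no_treatment``: apixaban-monotherapy vs no treatment, per event;
      dividing the apixaban monotherapy rate by it recovers the untreated
      rate.
    * ``aging_per_decade``: multiplicative increase in event hazard per
      decade of life, applied after the first 6 months.
    * ``subsequent``: prior event -> future event risk multipliers
      (future MI fixed at 1.00).
    * ``postacute_mortality``: excess all-cause mortality vs the general
      population by event history (``event_free`` covers the no-event and
      OMB-history states).
    """

    no_treatment: dict
    aging_per_decade: dict
    subsequent: dict
    postacute_mortality: dict

    def validate(self) -> None:
        for ev in EVENTS:
            _require(self.no_treatment.get(ev, 0) > 0,
                     f"hr.no_treatment.{ev} must be > 0")
        for ev in ("MI", "IS", "ICH", "OMB"):
            _require(self.aging_per_decade.get(ev, 0) > 0,
                     f"hr.aging.{ev} must be > 0")
        for prior in LONG_TERM_EVENTS:
            for future in LONG_TERM_EVENTS:
                hr = self.subsequent[prior][future]
                _require(hr > 0, f"hr.subsequent.{prior}.{future} must be > 0")
                if future == "MI":
                    _require(hr == 1.0,
                             "future-MI hazard ratios are fixed at 1.00")
        for key in ("MI", "IS", "ICH", "event_free"):
            _require(self.postacute_mortality.get(key, 0) > 0,
                     f"hr.mortality.{key} must be > 0")


@dataclass
class FatalityTable:
    """Age-banded case fatality applied once in the acute cycle.

    Rows: (event, age_lo, age_hi, interval_days, cfr).  Bands are
    half-open ``[lo, hi)``; ages below the lowest band clamp to it.  All
    intervals are 30 or 90 days, i.e. at most one 3-month cycle.
    """

    rows: list

    def validate(self) -> None:
        by_event: dict = {}
        for ev, lo, hi, days, cfr in self.rows:
            _require(0.0 <= cfr <= 1.0, f"cfr.{ev} out of [0,1]: {cfr}")
            _require(days in (30, 90), f"cfr.{ev} interval_days must be 30/90")
            _require(lo < hi, f"cfr.{ev} empty age band")
            by_event.setdefault(ev, []).append((lo, hi))
        for ev, bands in by_event.items():
            bands.sort()
            for (l1, h1), (l2, _h2) in zip(bands, bands[1:]):
                _require(h1 <= l2, f"cfr.{ev} overlapping age bands")

    def cfr(self, event: str, age: float) -> float:
        bands = sorted((lo, hi, cfr) for ev, lo, hi, _d, cfr in self.rows
                       if ev == event)
        if not bands:
            return 0.0
        if age < bands[0][0]:          # clamp below the lowest band
            return bands[0][2]
        for lo, hi, cfr in bands:
            if lo <= age < hi:
                return cfr
        return bands[-1][2]

    def cfr_vector(self, event: str, ages: np.ndarray) -> np.ndarray:
        return np.array([self.cfr(event, a) for a in np.atleast_1d(ages)])


@dataclass
class DiscontinuationParams:
    """Treatment discontinuation probabilities.

    ``per_event``: permanent discontinuation among survivors of the acute
    cycle of each long-term event.  ``per_cycle_unrelated``: per-cycle
    probability of stopping for reasons unrelated to clinical events, per
    arm.  Once off treatment, patients stay off for the rest of the
    horizon.
    """

    per_event: dict
    per_cycle_unrelated: dict
    interruption_cycles: int = 1

    def validate(self) -> None:
        for ev in LONG_TERM_EVENTS:
            p = self.per_event.get(ev, 0.0)
            _require(0.0 <= p <= 1.0, f"disc.event.{ev} out of [0,1]: {p}")
        for arm in ARMS:
            p = self.per_cycle_unrelated[arm]
            _require(0.0 <= p <= 1.0, f"disc.unrelated.{arm} out of [0,1]")
        _require(self.interruption_cycles >= 0,
                 "interruption_cycles must be >= 0")


@dataclass
class CostTable:
    """All unit costs (2019 euros).

    The per-cycle drug cost column is authoritative; per-mg prices are
    retained for provenance (several are printed rounded and do not
    reproduce the per-cycle figure).
    """

    drugs: dict                # agent -> {price_per_mg, daily_dose, cost_per_cycle}
    p2y12_shares: dict         # arm -> {agent: share}
    inr_cost_per_test: float
    acute: dict                # event -> one-off DRG cost
    maintenance_monthly: dict  # event -> €/month in post-acute states
    societal_acute: dict
    societal_monthly: dict

    def validate(self) -> None:
        for agent, d in self.drugs.items():
            _require(d["cost_per_cycle"] >= 0, f"cost.drug_cycle.{agent} < 0")
        for arm, shares in self.p2y12_shares.items():
            total = sum(shares.values())
            _require(abs(total - 1.0) <= 1e-9,
                     f"p2y12.{arm} shares sum to {total}, expected 1")
            _require(all(v >= 0 for v in shares.values()),
                     f"p2y12.{arm} has a negative share")
        _require(self.inr_cost_per_test >= 0, "cost.inr_test < 0")
        for ev in EVENTS:
            _require(self.acute.get(ev, 0) >= 0, f"cost.acute.{ev} < 0")
        for d in (self.maintenance_monthly, self.societal_acute,
                  self.societal_monthly):
            for ev, v in d.items():
                _require(v >= 0, f"negative cost for {ev}")


@dataclass
class UtilityTable:
    """EQ-5D baseline equation coefficients and event:control ratios.

    The baseline cohort utility is the UK general-population quadratic in
    age and male share; event decrements are multiplicative ratios (acute
    during the event cycle, post-acute per history event thereafter).
    """

    baseline_coeffs: dict      # intercept, male, age, age2
    acute_ratio: dict          # event -> ratio in (0, 1]
    post_ratio: dict           # long-term event -> ratio in (0, 1]
    acute_meta: dict = field(default_factory=dict)   # event/control means + SEs
    post_meta: dict = field(default_factory=dict)

    def validate(self, cohort_age: float = 69.9, male_share: float = 0.71) -> None:
        for ev in EVENTS:
            r = self.acute_ratio.get(ev)
            _require(r is not None and 0 < r <= 1.0,
                     f"util.acute.{ev}.ratio out of (0,1]: {r}")
        for ev in LONG_TERM_EVENTS:
            r = self.post_ratio.get(ev)
            _require(r is not None and 0 < r <= 1.0,
                     f"util.post.{ev}.ratio out of (0,1]: {r}")
        u0 = baseline_utility(cohort_age, male_share, self.baseline_coeffs)
        _require(0.0 < u0 < 1.0, f"baseline utility at cohort age is {u0}")


@dataclass
class CohortSpec:
    start_age: float = 69.9
    male_share: float = 0.71
    initial_postacute_mi_share: float = 0.612

    def validate(self) -> None:
        _require(self.start_age > 0, "cohort.start_age must be > 0")
        for name in ("male_share", "initial_postacute_mi_share"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"cohort.{name} out of [0,1]: {v}")


@dataclass
class LifeTable:
    """General-population annual death probabilities by integer age."""

    ages: np.ndarray
    qx: np.ndarray
    terminal_age: int = 100

    def validate(self) -> None:
        _require(len(self.ages) == len(self.qx), "life table shape mismatch")
        diffs = np.diff(self.ages)
        _require(np.all(diffs == 1), "life table ages must be contiguous")
        _require(np.all((self.qx >= 0) & (self.qx <= 1)),
                 "life table qx out of [0,1]")
        if self.ages[-1] >= self.terminal_age:
            idx = np.searchsorted(self.ages, self.terminal_age)
            _require(np.all(self.qx[idx:] == 1.0),
                     "qx must be 1 at and beyond the terminal age")

    def qx_at(self, age) -> np.ndarray:
        """qx at (possibly fractional) ages; clamps below the table minimum,
        returns 1 at and beyond the terminal age."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        idx = np.clip(np.floor(age).astype(int) - int(self.ages[0]),
                      0, len(self.ages) - 1)
        out = self.qx[idx]
        return np.where(age >= self.terminal_age, 1.0, out)


@dataclass
class StrategySchedule:
    """Cycle-indexed treatment phases: contiguous, step-down only."""

    blocks: list               # [(phase, start_cycle, end_cycle), ...]

    _ORDER = {"triple_or_dual": 0, "triple": 0, "dual": 1, "mono": 2}

    def validate(self, horizon: int) -> None:
        _require(len(self.blocks) > 0, "schedule has no blocks")
        _require(self.blocks[0][1] == 0, "schedule must start at cycle 0")
        prev_end, prev_rank = 0, -1
        for phase, start, end in self.blocks:
            _require(phase in ON_TREATMENT_PHASES, f"unknown phase {phase}")
            _require(start == prev_end, "schedule blocks must be contiguous")
            _require(end > start, "empty schedule block")
            rank = self._ORDER[phase]
            _require(rank > prev_rank or (prev_rank == -1),
                     "schedule must step down (no repeated or step-up phase)")
            prev_end, prev_rank = end, rank
        _require(prev_end >= horizon, "schedule does not cover the horizon")

    def phase_at(self, cycle: int) -> str:
        for phase, start, end in self.blocks:
            if start <= cycle < end:
                return phase
        return self.blocks[-1][0]

    def phases(self, horizon: int) -> list:
        return [self.phase_at(t) for t in range(horizon)]


@dataclass
class ModelConfig:
    """The complete parameter pack plus run settings for one model run."""

    rates: EventRateTable
    hrs: HazardRatioSet
    fatality: FatalityTable
    discontinuation: DiscontinuationParams
    costs: CostTable
    utilities: UtilityTable
    cohort: CohortSpec
    life_table: LifeTable
    cycle_length_years: float = 0.25
    cycle_days: float = 91.3125
    discount_rate_annual: float = 0.03
    terminal_age: int = 100
    perspective: str = "payer"
    wtp: float = 20000.0
    triple_share_in_blend: float = 0.5
    inr_tests_per_cycle: float = 4.5
    dirichlet_effective_count: float = 2306.0
    joint_hr_combination: str = "product"
    half_cycle_correction: bool = False
    vka_agent: str = "acenocoumarol"
    param_meta: dict = field(default_factory=dict, repr=False)

    @property
    def horizon(self) -> int:
        """Number of 3-month cycles until the cohort reaches the terminal age."""
        return max(1, math.ceil(
            (self.terminal_age - self.cohort.start_age) / self.cycle_length_years))

    def validate(self) -> None:
        _require(self.discount_rate_annual >= 0, "discount rate must be >= 0")
        _require(self.horizon >= 1, "horizon must be >= 1")
        _require(abs(self.cycle_days - DAYS_PER_YEAR * self.cycle_length_years)
                 < 1e-9, "cycle_days inconsistent with cycle_length_years")
        _require(self.perspective in ("payer", "societal"),
                 f"unknown perspective {self.perspective}")
        _require(self.wtp > 0, "wtp must be > 0")
        _require(0.0 <= self.triple_share_in_blend <= 1.0,
                 "triple_share_in_blend out of [0,1]")
        _require(self.inr_tests_per_cycle >= 0, "inr_tests_per_cycle < 0")
        _require(self.joint_hr_combination in ("product", "max"),
                 "joint_hr_combination must be 'product' or 'max'")
        _require(self.vka_agent in self.costs.drugs,
                 f"unknown VKA agent {self.vka_agent}")
        self.rates.validate()
        self.hrs.validate()
        self.fatality.validate()
        self.discontinuation.validate()
        self.costs.validate()
        self.cohort.validate()
        self.utilities.validate(self.cohort.start_age, self.cohort.male_share)
        self.life_table.validate()

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)


@dataclass
class ParamMeta:
    """Sampling/bound metadata for one scalar (or simplex) input."""

    pid: str
    dist: str                  # gamma | beta | lognormal | normal | dirichlet
    value: object
    se: float | None = None
    ci: tuple | None = None
    bounds: tuple | None = None   # hard truncation (e.g. age)
    in_dsa: bool = True


# ---------------------------------------------------------------------------
# Derived inputs
# ---------------------------------------------------------------------------

def derive_no_treatment_rates(mono_apixaban_rates: Mapping[str, float],
                              no_treatment_hrs: Mapping[str, float]) -> dict:
    """Off-treatment event rates shared by both arms.

    The published HR is apixaban-monotherapy vs no treatment, so dividing
    the apixaban monotherapy rate by it recovers the untreated rate.
    """
    out = {}
    for ev in EVENTS:
        hr = no_treatment_hrs[ev]
        if hr <= 0:
            raise ValidationError(f"hr.no_treatment.{ev} must be > 0")
        out[ev] = mono_apixaban_rates[ev] / hr
    return out


def weighted_p2y12_cost(shares: Mapping[str, float],
                        costs_per_cycle: Mapping[str, float]) -> float:
    """Share-weighted per-cycle cost of the P2Y12 inhibitor mix."""
    total = sum(shares.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"P2Y12 shares sum to {total}, expected 1")
    return sum(shares[a] * costs_per_cycle[a] for a in shares)


def baseline_utility(age: float, male_share: float,
                     coeffs: Mapping[str, float]) -> float:
    """General-population EQ-5D utility at a given age and male share."""
    return (coeffs["intercept"] + coeffs["male"] * male_share
            + coeffs["age"] * age + coeffs["age2"] * age ** 2)


# ---------------------------------------------------------------------------
# Pack I/O
# ---------------------------------------------------------------------------

def default_pack_path() -> Path:
    return Path(resources.files("apixvka").joinpath("data/pack"))


def default_life_table_path() -> Path:
    return Path(resources.files("apixvka").joinpath(
        "data/life_tables/spain_2019_synthetic.csv"))


def load_life_table(csv_source, terminal_age: int = 100) -> LifeTable:
    """Read a CSV with ``age,qx`` columns into a :class:`LifeTable`.

    qx is coerced to 1 at the terminal age (with a warning if it was not).
    """
    df = pd.read_csv(csv_source)
    if not {"age", "qx"}.issubset(df.columns):
        raise ValidationError("life table CSV needs 'age' and 'qx' columns")
    df = df.sort_values("age").reset_index(drop=True)
    ages = df["age"].to_numpy(dtype=int)
    qx = df["qx"].to_numpy(dtype=float)
    if np.any(np.diff(ages) != 1):
        raise ValidationError("life table has a gap in ages")
    if np.any((qx < 0) | (qx > 1)):
        raise ValidationError("life table qx outside [0,1]")
    mask = ages >= terminal_age
    if mask.any() and not np.all(qx[mask] == 1.0):
        import warnings
        warnings.warn(f"coercing qx to 1.0 at terminal age {terminal_age}",
                      stacklevel=2)
        qx = qx.copy()
        qx[mask] = 1.0
    lt = LifeTable(ages=ages, qx=qx, terminal_age=terminal_age)
    lt.validate()
    return lt


def _read_yaml(path: Path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_parameter_pack(pack_source=None, life_table=None) -> ModelConfig:
    """Load and validate a parameter pack into a :class:`ModelConfig`.

    ``pack_source`` is a directory holding the pack files (defaults to the
    shipped pack transcribed from the source trial/tariff inputs);
    ``life_table`` a :class:`LifeTable` or CSV path (defaults to the
    shipped synthetic Spain-2019-like table).
    """
    pack = Path(pack_source) if pack_source is not None else default_pack_path()
    for fname in ("settings.yaml", "cohort.yaml", "event_rates.csv",
                  "hazard_ratios.yaml", "fatality.csv", "discontinuation.yaml",
                  "costs.yaml", "utilities.yaml"):
        if not (pack / fname).exists():
            raise ValidationError(f"parameter pack is missing {fname}")

    settings = _read_yaml(pack / "settings.yaml")
    cohort_raw = _read_yaml(pack / "cohort.yaml")
    hr_raw = _read_yaml(pack / "hazard_ratios.yaml")
    disc_raw = _read_yaml(pack / "discontinuation.yaml")
    costs_raw = _read_yaml(pack / "costs.yaml")
    util_raw = _read_yaml(pack / "utilities.yaml")

    rates_df = pd.read_csv(pack / "event_rates.csv")
    rates: dict = {}
    ses: dict = {}
    for (phase, arm), grp in rates_df.groupby(["phase", "arm"]):
        rates[(phase, arm)] = dict(zip(grp["event"], grp["rate"]))
        ses[(phase, arm)] = dict(zip(grp["event"], grp["se"]))
    rate_table = EventRateTable(rates=rates, ses=ses)

    fat_df = pd.read_csv(pack / "fatality.csv")
    fat_rows = [(r.event, float(r.age_lo), float(r.age_hi),
                 int(r.interval_days), float(r.cfr))
                for r in fat_df.itertuples()]
    fatality = FatalityTable(rows=fat_rows)

    def _hr_block(block):
        return {k: float(v["value"]) for k, v in block.items()}

    hrs = HazardRatioSet(
        no_treatment=_hr_block(hr_raw["no_treatment"]),
        aging_per_decade=_hr_block(hr_raw["aging_per_decade"]),
        subsequent={p: _hr_block(hr_raw["subsequent_event"][p])
                    for p in hr_raw["subsequent_event"]},
        postacute_mortality=_hr_block(hr_raw["postacute_mortality"]),
    )

    disc = DiscontinuationParams(
        per_event={k: float(v["value"]) for k, v in disc_raw["per_event"].items()},
        per_cycle_unrelated={k: float(v["value"])
                             for k, v in disc_raw["per_cycle_unrelated"].items()},
        interruption_cycles=int(settings.get("interruption_cycles", 1)),
    )

    costs = CostTable(
        drugs={k: dict(v) for k, v in costs_raw["drugs"].items()},
        p2y12_shares={k: dict(v) for k, v in costs_raw["p2y12_shares"].items()},
        inr_cost_per_test=float(costs_raw["inr_monitoring"]["cost_per_test"]),
        acute={k: float(v) for k, v in costs_raw["acute_event"].items()},
        maintenance_monthly={k: float(v)
                             for k, v in costs_raw["maintenance_monthly"].items()},
        societal_acute={k: float(v) for k, v in costs_raw["societal_acute"].items()},
        societal_monthly={k: float(v)
                          for k, v in costs_raw["societal_monthly"].items()},
    )

    utilities = UtilityTable(
        baseline_coeffs={k: float(v)
                         for k, v in util_raw["baseline_coeffs"].items()},
        acute_ratio={k: float(v["ratio"]) for k, v in util_raw["acute"].items()},
        post_ratio={k: float(v["ratio"])
                    for k, v in util_raw["post_acute"].items()},
        acute_meta={k: dict(v) for k, v in util_raw["acute"].items()},
        post_meta={k: dict(v) for k, v in util_raw["post_acute"].items()},
    )

    cohort = CohortSpec(
        start_age=float(cohort_raw["start_age"]["value"]),
        male_share=float(cohort_raw["male_share"]["value"]),
        initial_postacute_mi_share=float(
            cohort_raw["initial_postacute_mi_share"]["value"]),
    )

    terminal_age = int(settings.get("terminal_age", 100))
    if life_table is None:
        life_table = load_life_table(default_life_table_path(), terminal_age)
    elif not isinstance(life_table, LifeTable):
        life_table = load_life_table(life_table, terminal_age)

    config = ModelConfig(
        rates=rate_table, hrs=hrs, fatality=fatality, discontinuation=disc,
        costs=costs, utilities=utilities, cohort=cohort, life_table=life_table,
        cycle_length_years=float(settings["cycle_length_years"]),
        cycle_days=float(settings["cycle_days"]),
        discount_rate_annual=float(settings["discount_rate_annual"]),
        terminal_age=terminal_age,
        perspective=str(settings.get("perspective", "payer")),
        wtp=float(settings.get("wtp", 20000.0)),
        triple_share_in_blend=float(settings.get("triple_share_in_blend", 0.5)),
        inr_tests_per_cycle=float(settings.get("inr_tests_per_cycle", 4.5)),
        dirichlet_effective_count=float(
            settings.get("dirichlet_effective_count", 2306)),
        joint_hr_combination=str(settings.get("joint_hr_combination", "product")),
        half_cycle_correction=bool(settings.get("half_cycle_correction", False)),
    )
    config.param_meta = _build_param_meta(config, cohort_raw, rates_df, hr_raw,
                                          disc_raw, costs_raw, util_raw, fat_df)
    config.validate()
    return config


def write_parameter_pack(config: ModelConfig, out_dir) -> Path:
    """Serialize a config back into pack files (round-trips through
    :func:`load_parameter_pack`)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    settings = {
        "cycle_length_years": config.cycle_length_years,
        "cycle_days": config.cycle_days,
        "discount_rate_annual": config.discount_rate_annual,
        "terminal_age": config.terminal_age,
        "perspective": config.perspective,
        "wtp": config.wtp,
        "triple_share_in_blend": config.triple_share_in_blend,
        "inr_tests_per_cycle": config.inr_tests_per_cycle,
        "interruption_cycles": config.discontinuation.interruption_cycles,
        "dirichlet_effective_count": config.dirichlet_effective_count,
        "joint_hr_combination": config.joint_hr_combination,
        "half_cycle_correction": config.half_cycle_correction,
    }
    with open(out / "settings.yaml", "w") as fh:
        yaml.safe_dump(settings, fh)

    meta = config.param_meta
    def _with_meta(pid, value):
        m = meta.get(pid)
        d = {"value": value}
        if m is not None and m.se is not None:
            d["se"] = m.se
        if m is not None and m.ci is not None:
            d["ci"] = list(m.ci)
        return d

    cohort = {
        "start_age": _with_meta("cohort.start_age", config.cohort.start_age),
        "male_share": _with_meta("cohort.male_share", config.cohort.male_share),
        "initial_postacute_mi_share":
            {"value": config.cohort.initial_postacute_mi_share},
    }
    with open(out / "cohort.yaml", "w") as fh:
        yaml.safe_dump(cohort, fh)

    rows = []
    for phase in ON_TREATMENT_PHASES:
        for arm in ARMS:
            for ev in EVENTS:
                rows.append({"phase": phase, "arm": arm, "event": ev,
                             "rate": config.rates.rates[(phase, arm)][ev],
                             "se": config.rates.ses[(phase, arm)][ev]})
    pd.DataFrame(rows).to_csv(out / "event_rates.csv", index=False)

    def _hr_out(block, prefix):
        return {k: _with_meta(f"{prefix}.{k}", v) for k, v in block.items()}

    hr_raw = {
        "no_treatment": _hr_out(config.hrs.no_treatment, "hr.no_treatment"),
        "aging_per_decade": _hr_out(config.hrs.aging_per_decade, "hr.aging"),
        "subsequent_event": {
            p: _hr_out(config.hrs.subsequent[p], f"hr.subsequent.{p}")
            for p in config.hrs.subsequent},
        "postacute_mortality": _hr_out(config.hrs.postacute_mortality,
                                       "hr.mortality"),
    }
    with open(out / "hazard_ratios.yaml", "w") as fh:
        yaml.safe_dump(hr_raw, fh)

    fat = pd.DataFrame(config.fatality.rows,
                       columns=["event", "age_lo", "age_hi",
                                "interval_days", "cfr"])
    fat.to_csv(out / "fatality.csv", index=False)

    disc_raw = {
        "per_event": {k: _with_meta(f"disc.event.{k}", v)
                      for k, v in config.discontinuation.per_event.items()},
        "per_cycle_unrelated": {
            k: _with_meta(f"disc.unrelated.{k}", v)
            for k, v in config.discontinuation.per_cycle_unrelated.items()},
    }
    with open(out / "discontinuation.yaml", "w") as fh:
        yaml.safe_dump(disc_raw, fh)

    costs_raw = {
        "drugs": config.costs.drugs,
        "p2y12_shares": config.costs.p2y12_shares,
        "inr_monitoring": {"cost_per_test": config.costs.inr_cost_per_test},
        "acute_event": config.costs.acute,
        "maintenance_monthly": config.costs.maintenance_monthly,
        "societal_acute": config.costs.societal_acute,
        "societal_monthly": config.costs.societal_monthly,
    }
    with open(out / "costs.yaml", "w") as fh:
        yaml.safe_dump(costs_raw, fh)

    util_raw = {
        "baseline_coeffs": config.utilities.baseline_coeffs,
        "acute": {ev: {**config.utilities.acute_meta.get(ev, {}),
                       "ratio": config.utilities.acute_ratio[ev]}
                  for ev in EVENTS},
        "post_acute": {ev: {**config.utilities.post_meta.get(ev, {}),
                            "ratio": config.utilities.post_ratio[ev]}
                       for ev in LONG_TERM_EVENTS},
    }
    with open(out / "utilities.yaml", "w") as fh:
        yaml.safe_dump(util_raw, fh)
    return out


# ---------------------------------------------------------------------------
# Parameter registry: stable IDs for DSA/PSA
# ---------------------------------------------------------------------------

def _build_param_meta(config, cohort_raw, rates_df, hr_raw, disc_raw,
                      costs_raw, util_raw, fat_df) -> dict:
    meta: dict = {}

    def add(pid, dist, value, se=None, ci=None, bounds=None, in_dsa=True):
        meta[pid] = ParamMeta(pid=pid, dist=dist, value=value, se=se, ci=ci,
                              bounds=bounds, in_dsa=in_dsa)

    add("cohort.start_age", "normal", config.cohort.start_age,
        se=float(cohort_raw["start_age"].get("se", 0.13)), bounds=(40.0, 90.0))
    n = float(cohort_raw["male_share"].get("n", 4614))
    p = config.cohort.male_share
    add("cohort.male_share", "beta", p, se=math.sqrt(p * (1 - p) / n))

    for r in rates_df.itertuples():
        add(f"rate.{r.phase}.{r.arm}.{r.event}", "gamma", float(r.rate),
            se=float(r.se))

    def _ci(entry):
        ci = entry.get("ci")
        return tuple(float(x) for x in ci) if ci else None

    for ev, entry in hr_raw["no_treatment"].items():
        if "tied_to" in entry:
            continue               # sampled through the event it is tied to
        add(f"hr.no_treatment.{ev}", "lognormal", float(entry["value"]),
            ci=_ci(entry))
    for ev, entry in hr_raw["aging_per_decade"].items():
        add(f"hr.aging.{ev}", "lognormal", float(entry["value"]), ci=_ci(entry))
    for prior, row in hr_raw["subsequent_event"].items():
        for future, entry in row.items():
            if _ci(entry) is None:
                continue           # fixed at 1.00, not varied
            add(f"hr.subsequent.{prior}.{future}", "lognormal",
                float(entry["value"]), ci=_ci(entry))
    for key, entry in hr_raw["postacute_mortality"].items():
        add(f"hr.mortality.{key}", "lognormal", float(entry["value"]),
            ci=_ci(entry))

    for ev, entry in disc_raw["per_event"].items():
        if entry.get("se") is None:
            continue               # MI/IS: no event-related discontinuation
        add(f"disc.event.{ev}", "beta", float(entry["value"]),
            se=float(entry["se"]))
    for arm, entry in disc_raw["per_cycle_unrelated"].items():
        add(f"disc.unrelated.{arm}", "beta", float(entry["value"]),
            se=float(entry["se"]))

    for i, r in enumerate(fat_df.itertuples()):
        add(f"cfr.{r.event}.{i}", "beta", float(r.cfr))

    for agent, d in costs_raw["drugs"].items():
        if float(d["cost_per_cycle"]) > 0:
            add(f"cost.drug_cycle.{agent}", "gamma", float(d["cost_per_cycle"]))
    add("cost.inr_test", "gamma", config.costs.inr_cost_per_test)
    for ev, v in costs_raw["acute_event"].items():
        add(f"cost.acute.{ev}", "gamma", float(v))
    for ev, v in costs_raw["maintenance_monthly"].items():
        if float(v) > 0:
            add(f"cost.maintenance.{ev}", "gamma", float(v))
    for ev, v in costs_raw["societal_acute"].items():
        add(f"cost.societal_acute.{ev}", "gamma", float(v))
    for ev, v in costs_raw["societal_monthly"].items():
        add(f"cost.societal_monthly.{ev}", "gamma", float(v))

    def _ratio_se(entry):
        # delta-method SE of the event:control utility ratio
        m_e, s_e = float(entry["event"]), float(entry["event_se"])
        m_c, s_c = float(entry["control"]), float(entry["control_se"])
        r = m_e / m_c
        return r * math.sqrt((s_e / m_e) ** 2 + (s_c / m_c) ** 2)

    for ev, entry in util_raw["acute"].items():
        add(f"util.acute.{ev}.ratio", "beta", float(entry["ratio"]),
            se=_ratio_se(entry))
    for ev, entry in util_raw["post_acute"].items():
        add(f"util.post.{ev}.ratio", "beta", float(entry["ratio"]),
            se=_ratio_se(entry))

    for arm, shares in costs_raw["p2y12_shares"].items():
        add(f"p2y12.{arm}", "dirichlet",
            tuple(float(shares[a]) for a in ("clopidogrel", "prasugrel",
                                             "ticagrelor")),
            in_dsa=False)
    return meta


def get_param(config: ModelConfig, pid: str):
    """Read the current value of a registered parameter."""
    parts = pid.split(".")
    if parts[0] == "cohort":
        return getattr(config.cohort, parts[1])
    if parts[0] == "rate":
        return config.rates.rates[(parts[1], parts[2])][parts[3]]
    if parts[0] == "hr":
        if parts[1] == "no_treatment":
            return config.hrs.no_treatment[parts[2]]
        if parts[1] == "aging":
            return config.hrs.aging_per_decade[parts[2]]
        if parts[1] == "subsequent":
            return config.hrs.subsequent[parts[2]][parts[3]]
        if parts[1] == "mortality":
            return config.hrs.postacute_mortality[parts[2]]
    if parts[0] == "disc":
        if parts[1] == "event":
            return config.discontinuation.per_event[parts[2]]
        return config.discontinuation.per_cycle_unrelated[parts[2]]
    if parts[0] == "cfr":
        idx = int(parts[2])
        return config.fatality.rows[idx][4]
    if parts[0] == "cost":
        c = config.costs
        if parts[1] == "drug_cycle":
            return c.drugs[parts[2]]["cost_per_cycle"]
        if parts[1] == "inr_test":
            return c.inr_cost_per_test
        if parts[1] == "acute":
            return c.acute[parts[2]]
        if parts[1] == "maintenance":
            return c.maintenance_monthly[parts[2]]
        if parts[1] == "societal_acute":
            return c.societal_acute[parts[2]]
        if parts[1] == "societal_monthly":
            return c.societal_monthly[parts[2]]
    if parts[0] == "util":
        if parts[1] == "acute":
            return config.utilities.acute_ratio[parts[2]]
        return config.utilities.post_ratio[parts[2]]
    if parts[0] == "p2y12":
        shares = config.costs.p2y12_shares[parts[1]]
        return tuple(shares[a] for a in ("clopidogrel", "prasugrel",
                                         "ticagrelor"))
    raise KeyError(f"unknown parameter id {pid}")


def set_param(config: ModelConfig, pid: str, value) -> None:
    """Write a registered parameter in place (tied inputs follow)."""
    parts = pid.split(".")
    if parts[0] == "cohort":
        setattr(config.cohort, parts[1], float(value))
        return
    if parts[0] == "rate":
        config.rates.rates[(parts[1], parts[2])][parts[3]] = float(value)
        return
    if parts[0] == "hr":
        if parts[1] == "no_treatment":
            config.hrs.no_treatment[parts[2]] = float(value)
            for st, lt in TIED_NO_TREATMENT_HR.items():
                if lt == parts[2]:
                    config.hrs.no_treatment[st] = float(value)
            return
        if parts[1] == "aging":
            config.hrs.aging_per_decade[parts[2]] = float(value)
            return
        if parts[1] == "subsequent":
            config.hrs.subsequent[parts[2]][parts[3]] = float(value)
            return
        if parts[1] == "mortality":
            config.hrs.postacute_mortality[parts[2]] = float(value)
            return
    if parts[0] == "disc":
        if parts[1] == "event":
            config.discontinuation.per_event[parts[2]] = float(value)
        else:
            config.discontinuation.per_cycle_unrelated[parts[2]] = float(value)
        return
    if parts[0] == "cfr":
        idx = int(parts[2])
        ev, lo, hi, days, _ = config.fatality.rows[idx]
        config.fatality.rows[idx] = (ev, lo, hi, days, float(value))
        return
    if parts[0] == "cost":
        c = config.costs
        if parts[1] == "drug_cycle":
            c.drugs[parts[2]]["cost_per_cycle"] = float(value)
        elif parts[1] == "inr_test":
            c.inr_cost_per_test = float(value)
        elif parts[1] == "acute":
            c.acute[parts[2]] = float(value)
        elif parts[1] == "maintenance":
            c.maintenance_monthly[parts[2]] = float(value)
        elif parts[1] == "societal_acute":
            c.societal_acute[parts[2]] = float(value)
        elif parts[1] == "societal_monthly":
            c.societal_monthly[parts[2]] = float(value)
        else:
            raise KeyError(pid)
        return
    if parts[0] == "util":
        v = float(value)
        if parts[1] == "acute":
            config.utilities.acute_ratio[parts[2]] = v
        else:
            config.utilities.post_ratio[parts[2]] = v
        return
    if parts[0] == "p2y12":
        agents = ("clopidogrel", "prasugrel", "ticagrelor")
        config.costs.p2y12_shares[parts[1]] = dict(zip(agents, map(float, value)))
        return
    raise KeyError(f"unknown parameter id {pid}")
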