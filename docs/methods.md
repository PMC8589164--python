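# Methods

This note documents the model as implemented: its structure, the
conventions chosen where the underlying evidence base is silent, what the
synthetic inputs do and do not emulate, and the numerical details a
maintainer would need.

## Cohort and setting

The modelled cohort enters at mean age 69.9 (71% male) within 14 days of
an ACS and/or PCI while having non-valvular AF; 61.2% start in the
post-acute-MI state (recent infarction), the rest event-free. Cycles are 3
months (91.3125 days = 365.25/4, back-derived from the per-cycle drug
costs), and the horizon runs to age 100 (121 cycles). Costs and health
outcomes are discounted at 3% per year, pro-rated per cycle,
(1+r)^(−0.25·cycle).

## State space

55 states: history ⊆ {MI, IS, ICH, OMB} with |history| ≤ 2, phase
(event-free / acute / post-acute), treatment status (on/off), plus Dead.
The acute phase lasts exactly one cycle, then the patient moves to the
post-acute state for that history. Once two distinct events have occurred
only those two can recur; a recurrence re-enters the same acute state.
Short-term events (CRNMB, REV, SE) never change state: their per-cycle
probabilities act as intensities that carry a one-cycle cost and a
one-cycle multiplicative disutility.

## Hazards and transition probabilities

Per cycle and origin state, the long-term event hazards are

    r_e = base_rate(phase or off, arm, e) × HR_aging(e)^((age − ref)/10)
          × Π_{prior ∈ history} HR_subsequent(prior → e)

with rates in events per 100 patient-years. The aging reference is the
cohort age at month 6 (the trial-covered period carries no aging
adjustment); aging HRs exist only for the four long-term events.
Off-treatment rates are the apixaban monotherapy rates divided by the
apixaban-vs-no-treatment HRs (shared by both arms); the short-term events
borrow the HR of a clinically similar long-term event (CRNMB~OMB, REV~MI,
SE~IS). Rates convert to probabilities by the competing-risk formula
p_e = (r_e/Σr)(1 − e^(−Σr·t)) over the allowed long-term events; the
short-term intensities are single-cause conversions 1 − e^(−r·t).

Each cycle, background mortality acts first as an independent cause:
p_bg = 1 − (1 − qx)^(0.25·HR_state), where HR_state is the post-acute
excess-mortality HR of the history (MI 1.45, IS 2.60, ICH 2.20; 1.16 for
event-free and, conservatively, OMB-only histories, which have no
published excess-mortality estimate; two-event histories multiply their
HRs). Survivors experience the competing events; each incident event
splits by its age-banded case fatality (applied once — all fatality
windows are ≤ one cycle) into death vs the acute state. Rows sum to 1 by
construction and are asserted to 1e-12.

Discontinuation moves on→off permanently: event-related among acute-cycle
survivors of OMB (25%) and ICH (55.8%), and a per-cycle
unrelated probability (apixaban 4.54%, VKA 4.80%) applied to the no-event
flow in every on-treatment phase from the first transition (the source
trial covers the first 6 months, so the blended phase is not exempt).

## Costs and utilities

* **Drug costs** use the authoritative per-cycle column (several per-mg
  prices are printed rounded and are internally inconsistent; apixaban,
  acenocoumarol and prasugrel reproduce their per-cycle figures to the
  cent, which pins the cycle length). The blended phase charges OAC +
  share-weighted P2Y12 + aspirin for the 50% triple half. Patients in an
  acute cycle interrupt treatment for `interruption_cycles` (default 1)
  cycles: a drug/monitoring-cost-only haircut that does not alter risks.
  For the default of one cycle the haircut (the on-treatment acute
  occupancy) is exact; longer interruptions are approximated by lagged
  acute occupancy.
* **Monitoring** applies to the VKA arm only: €7.05 per INR test ×
  `inr_tests_per_cycle`. The test frequency is nowhere published; the
  default 4.5/cycle (≈18/year) is a fixed convention exposed in the
  configuration. Under this engine it implies a lifetime discounted
  monitoring cost of ≈ €466 per VKA patient.
* **Acute event costs** (DRG tariffs) are charged per incident event in
  the event's cycle, including events in the cycle of death. **Maintenance
  costs** (€/month × 3) accrue from the event cycle onwards for every
  event in the state's history — the acute cycle of a second event already
  carries the maintenance of both events. An earlier draft started
  maintenance one cycle later; the published component totals
  (post-acute cost levels per arm) are reproducible only with accrual
  from the event cycle, so that convention is the implemented one.
* **Societal perspective** adds the indirect acute and monthly rows
  (printed only for IS and ICH) on top of payer costs.
* **Utilities** start from the UK general-population EQ-5D quadratic in
  age and male share (decreasing with age along the trace) and multiply:
  the acute ratio of the incident event, the post-acute ratios of prior
  history events, and intensity-weighted short-term ratios. QALYs and LYs
  accrue at cycle start (no half-cycle correction by default; a
  configuration switch enables mid-cycle averaging). Reported time
  on/off treatment is discounted, so the two add up to discounted life
  years, matching the convention of the published results table.

## Sensitivity analyses

DSA bounds: printed 95% CIs; else mean ± 1.96·SE; else ±10%. Beta-bounded
quantities clip to [0,1]. Parameters are ranked by absolute INMB swing.

PSA distributions are moment-matched: gamma (shape m²/v, rate m/v) for
rates and costs, beta for probabilities and utility ratios, lognormal for
HRs with σ = (ln U − ln L)/3.92 (±10% bounds standing in when no CI is
printed), truncated normal (40, 90) for age, Dirichlet (shares × effective
count, default 2,306 ≈ half the source trial) for the P2Y12 mix. Where no
SE is printed (costs, case fatality) the ±10% DSA convention supplies a
proxy SE of 0.1·mean/1.96; an explicit SE of 0 makes a distribution
degenerate. Utility decrements are sampled directly as beta-distributed
ratios with delta-method SEs from the printed event/control means — this
keeps the base case exactly at the printed ratios and makes the DSA
zero-swing identity exact. Parameters are sampled independently (no
correlation structure is published). Draws are reproducible from a seed.

The CEAC reports, per willingness-to-pay value, the share of draws with
positive net benefit (ties count one half).

## Synthetic inputs and oracles

The national life table cannot be redistributed here, so the package ships
a synthetic stand-in: Gompertz mortality qx = 1 − exp(−(a/b)e^(b·age)(e^b −
1)) with slope b = 0.11 (the textbook value for modern low-mortality
populations, matching Spain-2019-like old-age mortality, q90 ≈ 0.13) and
level a calibrated by numerical search to a period life expectancy at
birth of ≈ 83 years; the resulting e70 ≈ 16.4 matches the 71%-male-weighted
Spanish value. The stand-in reproduces aggregate survival, not cohort
effects, accident humps, or sex-specific tables — green tests establish
engine correctness and result stability under a realistic mortality
schedule, not agreement with official statistics.

Two oracles check the engine independently: (i) an individual-level
microsimulation that samples paths from the same per-cycle transition
rows and accrues per-individual discounted outcomes (state-conditional
expectations for incident-event and short-term costs keep the estimator
unbiased with lower variance) — it validates propagation and accrual;
(ii) a scalar brute-force transition-matrix builder sharing no engine
code — it validates the rate arithmetic, exercised on an IS/ICH-only
reduced model and on the full model.

## Design choices on open points

* Joint-state multipliers (subsequent-event HRs and excess-mortality HRs)
  combine multiplicatively across the two history events
  (proportional-hazards independence); `joint_hr_combination="max"` is
  available as the alternative.
* Blended-phase rates are used as printed; the 50/50 triple/dual split
  affects drug cost only.
* Ranged switch points for the alternative strategies default to the
  latest stated month (9 for triple→dual→mono, 12 for dual→mono).
* The alternative event-related discontinuation scenario is a
  configuration hook (`disc_event_override`) accepting user-supplied
  probabilities; no numeric values are published for it.
* Events from acute states are allowed (an acute cycle does not protect
  against further events).

## Limitations

* The trial-derived rates are extrapolated as constant hazards over a
  lifetime (aging HRs aside), as in the source analyses.
* The interruption mechanism is cost-side only and exact only for the
  default one-cycle interruption.
* No parameter correlations in PSA; no value-of-information analysis.
* The synthetic life table is a stand-in: absolute LY/QALY levels shift
  slightly with the mortality schedule, though incremental results are
  robust (the arms share background mortality).
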