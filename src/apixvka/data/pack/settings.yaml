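# Run settings for the base-case analysis.
cycle_length_years: 0.25
cycle_days: 91.3125           # 365.25 / 4; consistent with the per-cycle drug costs
discount_rate_annual: 0.03
terminal_age: 100             # lifetime horizon: cohort followed until age 100
perspective: payer            # payer | societal
wtp: 20000.0                  # €/QALY willingness-to-pay threshold
triple_share_in_blend: 0.5    # share of the "triple or dual" cohort on triple therapy (cost side)
inr_tests_per_cycle: 4.5      # INR monitoring frequency for VKA (~18 tests/year)
interruption_cycles: 1        # post-event treatment interruption, drug-cost side only
dirichlet_effective_count: 2306  # effective sample size for P2Y12-share Dirichlet sampling
joint_hr_combination: product    # how HRs combine in two-event histories: product | max
half_cycle_correction: false
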