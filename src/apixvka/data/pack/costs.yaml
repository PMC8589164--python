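# Costs in 2019 euros. Gamma-distributed in PSA (±10% bounds when no SE).
# The per-cycle column is authoritative: for agents whose per-mg price is
# printed rounded (aspirin, clopidogrel, ticagrelor) price x dose x 91.3125
# does not reproduce the per-cycle figure, while it does to the cent for
# apixaban, acenocoumarol and prasugrel.
drugs:
  apixaban:      {price_per_mg: 0.19, daily_dose: 10,  cost_per_cycle: 173.49}
  acenocoumarol: {price_per_mg: 0.03, daily_dose: 5,   cost_per_cycle: 13.70}
  warfarin:      {price_per_mg: 0.02, daily_dose: 5,   cost_per_cycle: 9.13125}
  aspirin:       {price_per_mg: 0.00, daily_dose: 81,  cost_per_cycle: 3.58}
  clopidogrel:   {price_per_mg: 0.01, daily_dose: 75,  cost_per_cycle: 54.82}
  prasugrel:     {price_per_mg: 0.07, daily_dose: 10,  cost_per_cycle: 63.92}
  ticagrelor:    {price_per_mg: 0.02, daily_dose: 120, cost_per_cycle: 194.81}
p2y12_shares:           # P2Y12 mix observed per arm; Dirichlet-distributed in PSA
  apixaban: {clopidogrel: 0.934, prasugrel: 0.012, ticagrelor: 0.054}
  vka:      {clopidogrel: 0.918, prasugrel: 0.011, ticagrelor: 0.071}
inr_monitoring:
  cost_per_test: 7.05   # € per INR analysis, VKA only
acute_event:            # one-off hospital (DRG) cost at the event
  OMB:   3341.59
  CRNMB: 2412.85
  MI:    4153.47
  IS:    5094.95
  ICH:   5987.77
  REV:   15599.15
  SE:    3875.89
maintenance_monthly:    # €/month while in a post-acute state with this history
  OMB: 0.0
  MI:  168.12
  IS:  1494.37
  ICH: 1494.37
societal_acute:         # indirect (societal) one-off event costs
  IS:  516.37
  ICH: 516.37
societal_monthly:       # indirect €/month in post-acute states
  IS:  1610.38
  ICH: 1610.38
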