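# Utilities. The baseline cohort utility comes from the UK general-population
# EQ-5D equation evaluated at the cohort's age and male share; event-related
# decrements are event:control ratios applied multiplicatively to it.
# event/control means (with SEs, beta-distributed in PSA) back the ratios;
# the printed ratio is the base-case value.
baseline_coeffs:
  intercept: 0.9454933
  male: 0.0256466
  age: -0.0002213
  age2: -0.0000294
acute:                  # applied during the event cycle (long- and short-term)
  OMB:   {ratio: 0.965, event: 0.808, event_se: 0.014, control: 0.837, control_se: 0.001}
  CRNMB: {ratio: 0.988, event: 0.826, event_se: 0.007, control: 0.836, control_se: 0.002}
  MI:    {ratio: 0.857, event: 0.690, event_se: 0.011, control: 0.805, control_se: 0.081}
  IS:    {ratio: 0.771, event: 0.640, event_se: 0.016, control: 0.830, control_se: 0.012}
  ICH:   {ratio: 0.675, event: 0.560, event_se: 0.077, control: 0.830, control_se: 0.012}
  REV:   {ratio: 0.975, event: 0.780, event_se: 0.016, control: 0.800, control_se: 0.012}
  SE:    {ratio: 0.879, event: 0.730, event_se: 0.014, control: 0.830, control_se: 0.012}
post_acute:             # applied every cycle spent with the event in history
  OMB: {ratio: 0.990, event: 0.829, event_se: 0.083, control: 0.837, control_se: 0.001}
  MI:  {ratio: 0.878, event: 0.702, event_se: 0.006, control: 0.799, control_se: 0.080}
  IS:  {ratio: 0.825, event: 0.685, event_se: 0.008, control: 0.830, control_se: 0.012}
  ICH: {ratio: 0.849, event: 0.705, event_se: 0.044, control: 0.830, control_se: 0.012}
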