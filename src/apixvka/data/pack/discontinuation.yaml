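# Treatment discontinuation. All probabilities; beta-distributed in PSA.
per_event:              # permanent discontinuation given the event (survivors)
  OMB: {value: 0.250, se: 0.0250}
  ICH: {value: 0.558, se: 0.0689}
  MI:  {value: 0.0}
  IS:  {value: 0.0}
per_cycle_unrelated:    # per 3-month cycle, unrelated to clinical events
  apixaban: {value: 0.0454, se: 0.0045}
  vka:      {value: 0.0480, se: 0.0048}
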