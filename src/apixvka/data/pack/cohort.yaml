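# Baseline cohort: AF patients starting antithrombotic therapy within 14 days
# of ACS and/or PCI.
start_age:
  value: 69.9
  se: 0.13          # sampled from a truncated normal (40, 90) in PSA
male_share:
  value: 0.71
  n: 4614           # trial size behind the proportion; beta-distributed in PSA
initial_postacute_mi_share:
  value: 0.612      # share of the cohort starting in the post-acute MI state
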