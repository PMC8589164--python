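# Hazard ratios. CIs are 95% intervals; lognormal-distributed in PSA.
# Short-term events borrow the no-treatment HR of a clinically similar
# long-term event (CRNMB ~ OMB, REV ~ MI, SE ~ IS): see `tied_to`.
no_treatment:           # apixaban monotherapy vs no treatment
  OMB:   {value: 1.24, ci: [0.70, 2.26]}
  CRNMB: {value: 1.24, tied_to: OMB}
  MI:    {value: 0.44, ci: [0.20, 1.03]}
  IS:    {value: 0.26, ci: [0.18, 0.37]}
  ICH:   {value: 1.90, ci: [0.64, 6.49]}
  REV:   {value: 0.44, tied_to: MI}
  SE:    {value: 0.26, tied_to: IS}
aging_per_decade:       # applied after the first 6 months, on the hazard scale
  OMB: {value: 1.97, ci: [1.79, 2.16]}
  MI:  {value: 1.30, ci: [0.74, 2.01]}
  IS:  {value: 1.46, ci: [0.80, 2.16]}
  ICH: {value: 1.97, ci: [1.79, 2.16]}
subsequent_event:       # prior event -> risk of future event; future MI fixed at 1.00
  OMB:
    ICH: {value: 3.54, ci: [3.02, 4.17]}
    OMB: {value: 3.32, ci: [3.06, 3.60]}
    MI:  {value: 1.00}
    IS:  {value: 1.32, ci: [1.21, 1.44]}
  MI:
    ICH: {value: 1.00}
    OMB: {value: 1.00}
    MI:  {value: 1.00}
    IS:  {value: 1.00}
  IS:
    ICH: {value: 1.64, ci: [1.39, 1.94]}
    OMB: {value: 1.39, ci: [1.27, 1.52]}
    MI:  {value: 1.00}
    IS:  {value: 4.00, ci: [3.78, 4.22]}
  ICH:
    ICH: {value: 10.20, ci: [8.59, 12.20]}
    OMB: {value: 2.95, ci: [2.57, 3.39]}
    MI:  {value: 1.00}
    IS:  {value: 1.78, ci: [1.56, 2.03]}
postacute_mortality:    # excess mortality vs general population by event history
  MI:  {value: 1.45, ci: [1.38, 1.53]}
  IS:  {value: 2.60, ci: [2.30, 3.00]}
  ICH: {value: 2.20}                      # CI not reported
  event_free: {value: 1.16, ci: [1.10, 1.22]}  # prior ACS/PCI (history of angina)
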