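event,age_lo,age_hi,interval_days,cfr
ICH,65,75,30,0.181
ICH,75,85,30,0.268
ICH,85,inf,30,0.309
OMB,0,inf,90,0.020
MI,60,70,30,0.071
MI,70,80,30,0.109
MI,80,inf,30,0.316
IS,0,inf,90,0.109
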