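phase,arm,event,rate,se
triple_or_dual,apixaban,OMB,6.25,0.02
triple_or_dual,apixaban,CRNMB,18.25,0.03
triple_or_dual,apixaban,MI,6.65,0.02
triple_or_dual,apixaban,IS,1.18,0.01
triple_or_dual,apixaban,ICH,0.50,0.005
triple_or_dual,apixaban,REV,5.63,0.02
triple_or_dual,apixaban,SE,0.09,0.001
triple_or_dual,vka,OMB,9.23,0.02
triple_or_dual,vka,CRNMB,26.07,0.03
triple_or_dual,vka,MI,7.44,0.02
triple_or_dual,vka,IS,2.38,0.01
triple_or_dual,vka,ICH,1.30,0.01
triple_or_dual,vka,REV,5.94,0.02
triple_or_dual,vka,SE,0.10,0.001
triple,apixaban,OMB,8.98,0.04
triple,apixaban,CRNMB,24.90,0.07
triple,apixaban,MI,6.29,0.03
triple,apixaban,IS,1.46,0.02
triple,apixaban,ICH,0.72,0.01
triple,apixaban,REV,4.80,0.03
triple,apixaban,SE,0.09,0.001
triple,vka,OMB,11.66,0.05
triple,vka,CRNMB,36.40,0.09
triple,vka,MI,6.31,0.03
triple,vka,IS,2.21,0.02
triple,vka,ICH,1.64,0.02
triple,vka,REV,5.38,0.03
triple,vka,SE,0.10,0.001
dual,apixaban,OMB,4.17,0.03
dual,apixaban,CRNMB,12.30,0.05
dual,apixaban,MI,7.01,0.04
dual,apixaban,IS,0.91,0.01
dual,apixaban,ICH,0.33,0.01
dual,apixaban,REV,6.46,0.03
dual,apixaban,SE,0.09,0.001
dual,vka,OMB,8.06,0.04
dual,vka,CRNMB,19.00,0.06
dual,vka,MI,8.57,0.04
dual,vka,IS,2.56,0.02
dual,vka,ICH,1.14,0.01
dual,vka,REV,6.50,0.03
dual,vka,SE,0.10,0.001
mono,apixaban,OMB,2.12,0.003
mono,apixaban,CRNMB,2.08,0.001
mono,apixaban,MI,0.95,0.002
mono,apixaban,IS,0.97,0.001
mono,apixaban,ICH,0.27,0.001
mono,apixaban,REV,1.69,0.003
mono,apixaban,SE,0.09,0.001
mono,vka,OMB,2.32,0.004
mono,vka,CRNMB,2.99,0.001
mono,vka,MI,1.00,0.002
mono,vka,IS,1.05,0.001
mono,vka,ICH,0.73,0.002
mono,vka,REV,1.89,0.003
mono,vka,SE,0.10,0.001
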