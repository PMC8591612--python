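name,delta_MPa05,V_cm3mol,s75,s21
acetone,20.0,74.1,1.00,0.12
THF,19.4,81.0,1.01,0.11
DXN,20.5,85.5,1.04,0.13
DMSO,26.7,71.0,1.04,0.009
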