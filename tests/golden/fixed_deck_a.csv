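well,template_slot,primer_slot,template_vol_ul,primer_vol_ul
A1,T1,P1,1.0,1.0
B1,T2,P2,1.0,1.0
C1,T3,P3,1.0,1.0
G12,T4,P4,1.0,1.0
H12,T5,P5,1.0,1.0
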