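well,template_name,primer_name,template_vol_ul,primer_vol_ul,mix_vol_ul,water_vol_ul
A1,pUC19,M13F,2.0,1.0,4.0,3.0
B1,pET28a,oligo001,1.0,0.5,4.0,4.5
C1,pGEX,T7,4.0,1.0,4.0,1.0
G12,R.Control,R.Control,1.0,1.0,4.0,4.0
H12,I.Control,I.Control,1.0,1.0,4.0,4.0
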