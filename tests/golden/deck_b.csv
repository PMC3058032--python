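template_name,well,template_vol_ul,primer_name,primer_vol_ul,mix_vol_ul,water_vol_ul
pUC19,A1,2.0,M13F,1.0,4.0,3.0
pET28a,B1,1.0,oligo001,0.5,4.0,4.5
pGEX,C1,4.0,T7,1.0,4.0,1.0
R.Control,G12,1.0,R.Control,1.0,4.0,4.0
I.Control,H12,1.0,I.Control,1.0,4.0,4.0
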