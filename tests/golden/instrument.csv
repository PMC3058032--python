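well,display_name,run_name,sample_ref
A1,pUC19_M13F,A1,S000001
B1,pET28a_oligo001,A1,S000002
C1,pGEX_T7,A1,S000003
G12,R.Control,A1,
H12,I.Control,A1,
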