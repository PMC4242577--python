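area_a,area_b
Beringia,N_Cascades
Olympics,N_Cascades
Olympics,S_Cascades
N_Cascades,S_Cascades
N_Cascades,C_Rockies
S_Cascades,C_Rockies
C_Rockies,S_Rockies
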