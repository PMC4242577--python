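taxon,Beringia,Olympics,N_Cascades,S_Cascades,C_Rockies,S_Rockies
aurita,1,0,0,0,0,0
lasiocarpa,1,0,1,0,0,0
idahoensis,0,0,0,0,1,0
parryi,0,0,0,0,1,1
piperi,0,1,0,0,0,0
scabrella,0,0,1,1,0,0
scouleri,0,1,0,1,0,0
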