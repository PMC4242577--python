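character,aurita_mean,aurita_sd,lasiocarpa_mean,lasiocarpa_sd,idahoensis_mean,idahoensis_sd,parryi_mean,parryi_sd,piperi_mean,piperi_sd,scabrella_mean,scabrella_sd,scouleri_mean,scouleri_sd
corolla_height_width,0.3,0.1,1.0,0.2,1.0,0.2,0.8,0.1,0.5,0.1,0.6,0.3,0.4,0.2
corolla_width,22.6,3.9,23.3,4.4,10.6,2.7,19.1,5.2,20.8,3.9,13.7,4.4,9.4,3.2
corolla_height,7.9,1.9,22.8,2.2,10.0,1.5,15.1,1.8,9.5,2.3,7.0,1.6,3.8,0.8
corolla_length,12.2,1.7,25.4,2.0,10.6,1.6,15.0,1.8,12.9,2.0,8.7,1.5,7.9,1.4
petal_lobe_length,10.3,1.8,9.2,1.0,3.9,0.4,7.9,1.7,9.5,1.4,6.0,1.4,4.4,1.2
fused_corolla_length,2.1,0.3,16.2,1.5,6.8,1.3,7.6,1.1,3.4,0.9,2.7,0.8,3.5,0.6
style_beyond_corolla,2.6,1.1,-8.2,1.7,-1.7,1.2,-6.5,1.6,1.3,2.6,0.2,1.5,8.6,1.2
style_stigma_length,11.0,1.6,13.5,1.7,8.2,1.2,8.7,1.8,8.8,1.6,6.5,1.4,12.8,1.0
sepal_length,5.2,1.4,8.5,1.2,3.8,1.9,10.5,3.2,5.3,1.2,3.6,1.0,4.7,1.8
petal_base_width,2.7,0.5,8.1,0.9,3.7,0.8,5.4,1.9,5.6,1.2,3.0,1.6,2.2,0.7
hypanthium_length,4.4,0.9,4.7,0.9,3.6,1.0,5.3,0.9,3.4,0.7,3.1,0.8,3.1,0.9
hypanthium_length_width,1.1,0.2,1.0,0.1,1.4,0.3,1.5,0.3,0.8,0.1,1.2,0.2,1.1,0.3
stem_length,163.0,40.3,46.1,20.3,117.5,39.7,160.0,53.1,30.1,13.8,38.4,18.3,187.5,89.8
hypanthium_width,4.1,0.5,4.7,1.0,2.7,0.4,3.7,0.7,4.2,0.7,2.6,0.6,2.8,0.4
seed_length,1.2,,0.7,,0.9,,0.6,,0.7,,0.85,,1.0,
seed_length_width,2.0,,2.0,,2.6,,1.8,,2.0,,2.4,,2.0,
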