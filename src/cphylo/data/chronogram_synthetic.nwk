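((piperi:560,aurita:560):470,((scouleri:510,parryi:510):260,(lasiocarpa:386,(scabrella:240,idahoensis:240):146):384):260):0;
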