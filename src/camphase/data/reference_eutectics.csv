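system,model,TE_C,xE
NAP-IND,ideal,128.1,0.55
NAP-IND,pcsaft,124.9,0.55
NAP-IBU,ideal,71.4,0.11
NAP-IBU,pcsaft,74.2,0.04
NAP-PRO,ideal,110.8,0.34
NAP-PRO,pcsaft,104.9,0.41
IND-PAR,ideal,132.2,0.48
IND-PAR,pcsaft,136.7,0.50
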