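system,TE_C,xE_tammann
NAP-IND,128.4,0.58
NAP-IBU,72.1,
NAP-PRO,120.5,0.33
IND-PAR,138.7,0.40
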