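system,model,k,q,Tg_NAP_C
NAP-IND,gordon_taylor,0.90,,7.9
NAP-IND,kwei,1.00,3.80,7.8
NAP-IBU,gordon_taylor,0.79,,9.8
NAP-IBU,kwei,1.00,-10.95,9.0
NAP-PRO,gordon_taylor,0.42,,1.7
NAP-PRO,kwei,2.14,36.47,2.2
IND-PAR,gordon_taylor,1.80,,
IND-PAR,kwei,3.08,8.54,
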