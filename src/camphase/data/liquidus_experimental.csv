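system,x1,TL_C
NAP-IND,0.1,156.2
NAP-IND,0.2,151.6
NAP-IND,0.6,129.8
NAP-IND,0.7,136.8
NAP-IND,0.8,146.3
NAP-IND,0.9,150.9
NAP-IBU,0.3,104.1
NAP-IBU,0.4,114.6
NAP-IBU,0.5,125.9
NAP-IBU,0.6,135.1
NAP-IBU,0.7,140.5
NAP-IBU,0.8,145.0
NAP-IBU,0.9,151.4
NAP-PRO,0.1,123.8
NAP-PRO,0.3,126.7
NAP-PRO,0.4,133.9
NAP-PRO,0.5,140.8
NAP-PRO,0.6,144.7
IND-PAR,0.1,168.2
IND-PAR,0.2,163.5
IND-PAR,0.3,156.7
IND-PAR,0.4,150.2
IND-PAR,0.5,145.6
IND-PAR,0.6,139.1
IND-PAR,0.7,144.2
IND-PAR,0.8,145.1
IND-PAR,0.9,151.5
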