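system,x1,dT_pcsaft_C,dT_ideal_C
NAP-IND,0.1,-0.4,-0.3
NAP-IND,0.2,-0.8,-0.5
NAP-IND,0.6,-0.4,2.7
NAP-IND,0.7,0.8,2.7
NAP-IND,0.8,-1.5,-0.6
NAP-IND,0.9,0.0,0.3
NAP-IBU,0.3,24.2,1.7
NAP-IBU,0.4,19.4,2.1
NAP-IBU,0.5,12.1,-0.3
NAP-IBU,0.6,6.2,-2.0
NAP-IBU,0.7,4.0,-0.7
NAP-IBU,0.8,2.9,0.7
NAP-IBU,0.9,0.3,-0.3
NAP-PRO,0.1,-1.9,-1.7
NAP-PRO,0.3,-14.9,-13.7
NAP-PRO,0.4,-28.6,-17.1
NAP-PRO,0.5,-24.7,-15.1
NAP-PRO,0.6,-18.3,-11.4
IND-PAR,0.1,-1.1,-1.5
IND-PAR,0.2,0.3,-1.4
IND-PAR,0.3,0.8,-2.4
IND-PAR,0.4,-2.0,-6.0
IND-PAR,0.5,-2.6,-5.6
IND-PAR,0.6,-1.6,-4.0
IND-PAR,0.7,2.3,0.9
IND-PAR,0.8,0.4,-0.2
IND-PAR,0.9,0.8,0.6
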