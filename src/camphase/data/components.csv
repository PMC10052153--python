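name,abbr,polymorph,structure_id,Tm_C,dHfus_kJmol,dCp_JKmol,Tg_C,m,sigma_A,eps_k_K,eps_assoc_k_K,kappa_assoc,donor_sites,acceptor_sites
indomethacin,IND,form gamma,INDMET,160.2,38.1,117.5,42.3,7.8970,3.8225,374.51,1295.43,0.01135,3,3
(RS)-ibuprofen,IBU,form I,IBPRAC,75.8,26.4,55.8,-43.8,5.4386,4.0179,309.40,516.469,0.08946,2,2
(S)-naproxen,NAP,form I,COYRUD11,156.0,32.4,99.3,6.4,4.4122,4.1142,470.92,1202.65,0.00952,2,2
paracetamol,PAR,form I,HXACAN34,168.2,27.1,99.8,25.7,3.2357,3.9819,432.09,1635.92,0.05432,2,2
probucol,PRO,form I,HAXHET01,126.0,35.3,124.7,22.0,11.8500,3.8500,375.62,1650.00,0.01000,2,2
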