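compound_id,mean_probability,cyp_inhibition,gi_absorption,bbb_permeant,lipinski_violations,risk_level,cyp2d6_maccs
isolaureline,61.5,1A2;2D6,High,Yes,0,HIGH,94.9
xylopine,59.9,1A2;2D6,High,Yes,0,HIGH,88.8
anonaine,55.9,1A2;2D6,High,Yes,0,HIGH,85.7
stepharine,32.5,1A2;2C19;2D6;3A4,High,Yes,0,HIGH,
coclaurine,34.1,2D6,High,Yes,0,MODERATE,
reticuline,31.0,2D6,High,Yes,0,MODERATE,
annonacin,14.1,3A4,Low,No,1,LOW,
swainsonine,10.7,None,High,No,0,LOW,
germacrene_d,20.1,2C9,Low,No,1,LOW,
e_caryophyllene,17.9,None,Low,Yes,0,LOW,
bullatacin,15.1,None,Low,No,1,NEGLIGIBLE,
annomuricin,14.1,None,Low,No,1,NEGLIGIBLE,
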