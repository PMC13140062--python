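compound_id,mw,clogp,gi_absorption,bbb_permeant,lipinski_violations,ba_score,cyp_inhibition,tpsa
anonaine,265.3,3.71,High,Yes,0,0.55,1A2;2D6,31.4
xylopine,295.3,2.62,High,Yes,0,0.55,1A2;2D6,40.6
isolaureline,309.4,3.28,High,Yes,0,0.55,1A2;2D6,40.6
coclaurine,285.3,2.14,High,Yes,0,0.55,2D6,63.9
reticuline,329.4,2.60,High,Yes,0,0.55,2D6,62.2
stepharine,323.4,2.69,High,Yes,0,0.55,1A2;2C19;2D6;3A4,41.9
swainsonine,173.2,-0.44,High,No,0,0.55,None,63.9
annonacin,552.8,7.15,Low,No,1,0.55,3A4,96.2
bullatacin,600.9,6.57,Low,No,1,0.55,None,119.6
annomuricin,613.0,8.24,Low,No,1,0.55,None,99.4
germacrene_d,218.4,4.88,Low,No,1,0.55,2C9,0.0
e_caryophyllene,162.3,3.27,Low,Yes,0,0.55,None,0.0
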