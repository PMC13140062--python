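compound_id,name,smiles,phytochemical_class
anonaine,Anonaine,C1Cc2cc3OCOc3c4c2C(N1)Cc5ccccc45,aporphine
xylopine,Xylopine,C1Cc2cc3OCOc3c4c2C(N1)Cc5ccc(OC)cc45,aporphine
isolaureline,Isolaureline,C1Cc2cc3OCOc3c4c2C(N1C)Cc5ccc(OC)cc45,aporphine
coclaurine,Coclaurine,COc1cc2CCNC(Cc3ccc(O)cc3)c2cc1O,benzylisoquinoline
reticuline,Reticuline,COc1cc2CCN(C)C(Cc3ccc(O)c(OC)c3)c2cc1O,benzylisoquinoline
stepharine,Stepharine,N1CCC2=CC(OC)=C(OC)C3=C2C1CC34C=CC(=O)C=C4,proaporphine
swainsonine,Swainsonine,OC1CCCN2CC(O)C(O)C12,indolizidine
annonacin,Annonacin,CCCCCCCCCCCCC(O)C1CCC(O1)C(O)CCCCC(O)CCCCCC(O)CC2=CC(C)OC2=O,acetogenin
bullatacin,Bullatacin,CCCCCCCCCCCC(O)C1CCC(O1)C2CCC(O2)C(O)CCCCCCCCCC(O)CC3=CC(C)OC3=O,acetogenin
annomuricin,Annomuricin,CCCCCCCCCCCCC(O)C1CCC(O1)C(O)CC(O)CC(O)CCCCCCC(O)CC2=CC(C)OC2=O,acetogenin
germacrene_d,Germacrene D,CC1=CCCC(=C)C=CC(C(C)C)CC1,sesquiterpene
e_caryophyllene,(E)-Caryophyllene,CC1=CCCC(=C)C2CC(C)(C)C2CC1,sesquiterpene
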