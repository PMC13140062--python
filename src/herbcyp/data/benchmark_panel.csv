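name,expected_isoform,CYP1A2_MACCS,CYP1A2_Morgan,CYP2C9_MACCS,CYP2C9_Morgan,CYP2C19_MACCS,CYP2C19_Morgan,CYP2D6_MACCS,CYP2D6_Morgan,CYP3A4_MACCS,CYP3A4_Morgan
ketoconazole,CYP3A4,,,,,,,,,100,99.0
quinidine,CYP2D6,,,,,,,98.2,98.7,,
fluvoxamine,CYP1A2,83.7,83.1,,,,,,,,
fluconazole,CYP2C9,,,52.5,,,,,,,
omeprazole,CYP2C19,,,,,99.1,70.4,,,,
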