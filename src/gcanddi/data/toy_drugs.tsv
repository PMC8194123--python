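drug_id	smiles	g1	g2	g3	g4	g5
DB_A	CCO	0.5	-1.2	0.3	2.1	-0.7
DB_B	c1ccccc1	1.1	0.4	-0.9	0.2	1.5
DB_C	CC(=O)Oc1ccccc1C(=O)O	-0.3	0.8	1.7	-1.1	0.6
DB_D	Cn1cnc2c1c(=O)n(C)c(=O)n2C	2.2	-0.5	0.1	0.9	-1.8
DB_E	CC(=O)Nc1ccc(O)cc1	-1.4	1.3	0.5	-0.2	0.8
DB_F	CC(C)Cc1ccc(cc1)C(C)C(=O)O	0.7	0.1	-1.6	1.2	0.4
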