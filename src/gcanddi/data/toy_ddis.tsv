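drug_a	drug_b	type_label
DB_A	DB_B	increased_hypoglycemia
DB_A	DB_C	increased_hypoglycemia
DB_B	DB_C	increased_hypoglycemia
DB_C	DB_A	increased_hypoglycemia
DB_D	DB_A	increased_hypoglycemia
DB_D	DB_B	increased_hypoglycemia
DB_E	DB_A	increased_hypoglycemia
DB_E	DB_B	increased_hypoglycemia
DB_F	DB_C	increased_hypoglycemia
DB_D	DB_E	qt_prolongation
DB_E	DB_F	qt_prolongation
DB_F	DB_D	qt_prolongation
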