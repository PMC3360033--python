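sample_id	subject_id	condition	cst	lactic_pct	acetic_pct	succinic_pct
S01_C1	S01	C1	II	9.6	1.6	2.8
S01_C2	S01	C2	NA	12.0	3.4	2.7
S01_C3	S01	C3	II	11.7	2.4	3.0
S02_C1	S02	C1	IV	11.6	5.0	6.2
S02_C2	S02	C2	IV	16.8	5.2	8.1
S02_C3	S02	C3	IV	10.8	5.6	8.2
S03_C1	S03	C1	IV	3.0	7.5	16.7
S03_C2	S03	C2	IV	3.1	7.8	17.3
S03_C3	S03	C3	IV	3.0	6.0	11.9
S04_C1	S04	C1	I	23.0	2.2	4.3
S04_C2	S04	C2	I	19.4	2.4	3.9
S04_C3	S04	C3	I	23.8	2.4	4.4
S05_C1	S05	C1	III	17.6	2.1	1.9
S05_C2	S05	C2	III	16.7	1.8	1.9
S05_C3	S05	C3	III	16.3	2.6	2.0
S06_C1	S06	C1	I	25.7	1.6	2.3
S06_C2	S06	C2	I	26.9	1.5	2.3
S06_C3	S06	C3	I	24.7	1.5	2.1
S07_C1	S07	C1	III	15.1	1.0	1.6
S07_C2	S07	C2	III	15.4	1.7	1.9
S07_C3	S07	C3	III	14.4	1.8	1.9
S08_C1	S08	C1	IV	6.3	1.3	1.6
S08_C2	S08	C2	IV	6.1	2.3	1.7
S08_C3	S08	C3	IV	6.2	2.2	1.5
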