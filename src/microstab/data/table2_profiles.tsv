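sample_id	subject_id	condition	cst	total_reads	L. iners	L. crispatus	Prevotella	L. gasseri	Atopobium	Megasphaera	Parvimonas	Sneathia	Lachnospiraceae.6	Lachnospiraceae.1	L. jensenii	Lachnospiraceae.4	Coriobacteriaceae.2	Mycoplasma	Dialister	Ruminococcaceae.3	Gemella	Gardnerella	Allisonella	Aerococcus
S01_C1	S01	C1	II	5788	0.3	0.0	3.0	90.7	0.1	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
S01_C3	S01	C3	II	8473	1.0	0.0	2.8	89.5	0.1	0.0	0.0	0.0	0.0	0.0	0.1	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
S02_C1	S02	C1	IV	5784	14.9	0.0	17.4	0.0	6.7	18.9	0.5	0.3	11.5	6.8	0.0	7.7	3.3	0.1	0.8	0.7	0.1	0.6	2.3	0.9
S02_C2	S02	C2	IV	9059	14.1	0.0	18.3	0.0	9.3	17.8	0.3	0.2	11.5	7.0	0.0	7.0	3.1	0.0	0.6	0.6	0.2	1.0	1.1	0.9
S02_C3	S02	C3	IV	6610	16.5	0.0	19.4	0.0	8.0	16.1	0.4	0.5	11.6	6.7	0.0	7.0	2.2	0.0	0.6	0.6	0.2	0.9	1.1	1.0
S03_C1	S03	C1	IV	7302	46.0	0.0	11.0	0.0	9.5	14.6	6.6	4.9	0.2	0.2	0.0	0.0	0.3	0.9	0.8	0.4	0.5	0.1	1.0	0.4
S03_C2	S03	C2	IV	10454	50.8	0.0	10.8	0.0	15.4	4.5	8.0	2.1	0.4	0.5	0.0	0.0	0.5	0.3	0.6	0.4	0.8	0.6	0.5	0.9
S03_C3	S03	C3	IV	18192	28.6	0.0	6.8	0.0	32.5	4.2	14.6	1.5	0.4	0.5	0.0	0.0	0.7	0.4	0.5	1.0	1.6	1.1	0.4	0.9
S04_C1	S04	C1	I	7129	42.8	42.9	0.1	0.2	0.0	0.0	0.0	0.0	0.0	0.0	7.6	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.1
S04_C2	S04	C2	I	4336	32.8	49.6	0.1	0.7	0.0	0.0	0.0	0.0	0.0	0.0	12.5	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.2
S04_C3	S04	C3	I	8740	39.6	46.6	0.1	0.3	0.0	0.0	0.0	0.0	0.0	0.0	6.9	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.1
S05_C1	S05	C1	III	6371	96.4	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.6	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
S05_C2	S05	C2	III	7491	97.5	0.0	0.0	0.1	0.0	0.0	0.0	0.0	0.0	0.0	0.8	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
S05_C3	S05	C3	III	8484	97.4	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.4	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
S06_C1	S06	C1	I	7574	0.0	98.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.2	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
S06_C2	S06	C2	I	8151	0.0	98.9	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.1	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
S06_C3	S06	C3	I	8174	0.0	98.3	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.1	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
S07_C1	S07	C1	III	6820	97.2	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
S07_C2	S07	C2	III	7315	97.6	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
S07_C3	S07	C3	III	5445	98.4	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
S08_C1	S08	C1	IV	10328	1.7	0.0	42.2	0.0	14.9	3.4	3.7	10.2	0.1	4.3	0.0	0.1	2.8	4.0	2.0	2.6	2.0	1.2	0.1	0.5
S08_C2	S08	C2	IV	4321	1.3	0.0	41.3	0.0	17.9	2.5	3.1	8.8	0.2	3.0	0.0	0.1	3.0	4.6	2.1	1.2	1.6	0.9	0.3	0.5
S08_C3	S08	C3	IV	4342	1.5	0.0	42.3	0.0	18.7	1.8	4.5	9.1	0.3	3.2	0.0	0.1	3.0	6.7	1.5	1.5	1.3	0.7	0.2	0.2
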