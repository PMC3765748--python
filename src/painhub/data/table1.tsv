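subject_id	group	gender	age	race	bdi	duration_yrs	bpi_avg
P01	patient	F	48	White	13	3	7
P02	patient	M	41	Asian	8	4	6
P03	patient	F	49	Black	30	8	6
P04	patient	F	47	Hisp.	7	3	10
P05	patient	F	23	White	1	10	3
P06	patient	M	27	White	0	10	3
P07	patient	F	23	White	4	3	3
P08	patient	M	38	White	0	2	4
P09	patient	M	25	Multi.	0	5	3
P10	patient	F	44	White	9	12	4
P11	patient	M	30	Multi.	5	10	9
P12	patient	F	31	Black	1	2	6
P13	patient	F	47	Black	3	5	8
P14	patient	F	46	Black	9	3	6
P15	patient	F	46	White	8	10	5
P16	patient	F	34	Black	10	3	8
P17	patient	M	26	White	0	1.5	2
P18	patient	F	25	Asian	9	0.5	2
C01	control	F	47	White
C02	control	M	37	Asian
C03	control	F	50	Black
C04	control	F	49	Black
C05	control	F	26	White
C06	control	M	30	White
C07	control	F	23	White
C08	control	M	39	White
C09	control	M	27	White
C10	control	F	45	White
C11	control	M	34	White
C12	control	F	32	Black
C13	control	F	47	Black
C14	control	F	46	Black
C15	control	F	47	White
C16	control	F	34	White
C17	control	M	27	White
C18	control	F	28	Asian
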