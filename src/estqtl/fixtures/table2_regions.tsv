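traits	chromosome	ci_lo_cM	ci_hi_cM	n_tc	n_stress_function	n_de
OP	1	86.6	86.6	13	0	
d13C, FF	2	64.0	77.6	31	1	1
Chl-a, d13C	3	76.0	76.6	6	5	1
OP, Chl-a	4	29.0	93.5	27	4	3
BW, DM, SC, HI	5	36.7	106.2	23	2	3
BW, HI	6	29.7	59.7	7	0	1
FS	6	138.8	139.4	2	0	
FS	7	91.2	131.4	12	1	2
SC, HI, BW, OP, d13C	7	167.0	217.0	50	20	5
Chl-a, Chl-b, d13C	8	44.9	52.3	10	2	1
OP, SC, HI, CT	10	77.5	122.2	57	20	8
d13C	11	44.0	56.7	17	6	5
OP	11	94.6	104.9	14	0	
SC, HI, BW	12	0.0	25.5	16	5	1
FL	12	38.8	43.1	32	8	2
OP, SC, HI, Chl-a	13	42.6	50.7	26	5	1
OP, BW	13	131.5	149.7	6	6	
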