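part	id	sts_marker	chromosome	position_cM	qtl	expression	putative_function	category
a	TC_12018	Coau2L06	2	75.8	d13C, FF		Calcium-dependent protein kinase 2	I′
a	TC_1043, 2901, 4773, 4777, 8848	pAR04H03	3	76.6	Chl-a, d13C		Xyloglucan endotransglucosylase/hydrolase protein	I′
a	TC_1191, 2292, 3741, 4297	pAR0594	4	87.2	Chl-a	↑ leaf	Putative transport protein subunit	II′
a	TC_15220, 5078	P05-06	5	36.7	DM	↑ leaf	Probable WRKY transcription factor	II′
a	TC_3299	pAR0207b	7	106.4	FS	↑ root	Putative linker histone H1 variant protein	II′
a	TC_3097, 6916, 8776	pAR03D05	7	172.1	SC		Putative CCR4 transcription complex	I′
a	TC_11788, 6599, 6600	Gafb22M15c	7	187.9	HI, BW, SC		Probable xyloglucan endotransglucosylase	I′
a	TC_12140, 370	pAR0922	7	202.3	HI, OP		stress-induced protein	I′
a	TC_11870, 12131, 4218, 5814, 9408	Unig24G08d	7	205.6	HI, OP		Luminal binding protein	I′
a	TC_3660, 5958	pGH843	7	207.4	HI, OP, d13C	↓ leaf	Ubiquitin/ribosomal protein	II′
a	TC_2075, 2076, 2077, 8440, 9924	pAR3-26	7	210.3	HI, OP, d13C	↓ leaf	Zinc finger	II′
a	TC_15720, 6936	Unig28D04	8	45.0	Chl-a, Chl-b, d13C	↓ leaf	ATP synthase	II′
a	TC_241, 8023, 8765	Gate4CE02	10	95.6	OP, SC, HI, CT	↑ leaf, ↓ root	Transcription factor WRKY1	II′
a	TC_1092	pAR0836	10	95.6	OP, SC, HI, CT		Photosystem II oxygen-evolving complex	I′
a	TC_4882	Gate4AH05	10	97.4	OP, SC, HI, CT	↑ root	Putative thioredoxin m2	II′
a	TC_7520, 7521, 7522, 7523, 7524	pAR0783	10	100.6	OP, SC, HI, CT		Auxin-repressed 12.5 KD protein	I′
a	TC_2988, 4865, 5435, 7627	Coau4J19	10	106.7	OP, SC, HI, CT		Protein induced upon tuberization	I′
a	TC_13398	Unig26D12	10	106.7	OP, SC, HI, CT		Putative GTP-binding protein	I′
a	TC_1142	pAR0949	10	112.7	OP, SC, HI, CT		Metallothionein-like protein	I′
a	TC_9516	pGH663	10	112.9	HI	↑ leaf	Homeobox-leucine zipper protein	II′
a	TC_159, 6239	pAR0211	10	114.5	HI		Heat shock protein 70	I′
a	TC_7534	Gate4CE05a	10	122	HI		MYB-like DNA-binding domain protein	I′
a	TC_3646, 3647, 3648	Gate1CE04b	11	45.7	d13C	↑ leaf	Ubiquitin extension protein	II′
a	TC_10672, 5735	pAR08A01	11	45.7	d13C	↑ root	Putative proline-rich protein	II′
a	TC_14408	Unig26E05	11	52.9	d13C	↑ leaf	Transcription initiation factor TFIID subunit 9	II′
a	TC_4402, 5648, 7125, 7127, 7134	Gate1CD11b	12	0.0	SC, HI, BW		Transducer (GPA1), Arabidopsis thaliana GPA1	I′
a	TC_12229, 12900, 12901	Gate4CG05a	12	38.8	FL		Soluble epoxide hydrolase	I′
a	TC_3419	Gate4CA09b	12	39.6	FL	↓ leaf	Zinc finger-like protein	II′
a	TC_11086	Gate4AE08b	12	40.4	FL		Hsp20.1 protein	I′
a	TC_3376, 7396, 7397	pVNC146b	12	41.5	FL		Omega-3 fatty acid desaturase, chloroplast precursor	I′
a	TC_3270, 3271, 3272, 4970, 8481	Gate4CG12	13	50.7	SC, HI		Thioredoxin-like protein 1	I′
a	TC_15659	Coau2L21	13	131.5	OP, BW		Adenylyl cyclase associated protein	I′
a	TC_4763, 8193, 8194, 8196, 8198	Gate1AA03	13	135.0	OP, BW		Glycine-rich RNA-binding protein	I′
b	Cotton12_00001_132	Gate3CC07a	2	76.2	d13C, FF	↓ leaf	Putative epimerase/dehydratase	II
b	Cotton12_00007_02	Coau1O15	3	76.0	Chl-a	↑ root, ↑ leaf	Unknown protein	II
b	Cotton12_18270_01	Gate4BG06a	4	74.4	Chl-a	↓ leaf	Homeobox-leucine zipper protein	II′
b	Cotton12_00128_02	Gate2BC04	4	103.5	Chl-a	↓ leaf	Unknown protein	II
b	Cotton12_14391_01	P05-06	5	36.7	DM	↓ leaf	F23H11.2 protein (At1g59710/T30E16_31)	II
b	Cotton12_07910_01	W07a	5	105.3	SC, HI, BW, FF	↓ leaf	Gossypium putative major latex-like protein	II
b	Cotton12_25608_01	A1737	6	49.8	HI, BW	↓ root	Hypothetical protein	II
b	Cotton12_00659_01	pAR0537	7	97.0	FS	↓ leaf	Putative glycine hydroxymethyltransferase	II
b	Cotton12_16738_01	pGH505	7	131.4	FS	↓ leaf	Hypothetical protein	II
b	Cotton12_00017_01	P01-42	7	192.6	SC, HI, BW	↓ leaf	RNA-binding protein	II
b	Cotton12_12667_01	P02-45	7	210.1	HI, OP, d13C	↑ leaf	Expressed protein	II
b	Cotton12_04174_01	Unig06B11	10	96.5	OP, SC, HI, CT, FS	↑ leaf	Hypothetical protein	II
b	Cotton12_04395_01	pAR10F02	10	100.6	OP, SC, HI, CT, FS	↑ leaf	Putative ethylene response factor ERF3a	II′
b	Cotton12_00370_02	pAR0602	10	108.2	OP, SC, HI, CT, FS	↓ leaf	ATP synthase gamma chain, chloroplast precursor	II′
b	Cotton12_01999_01	Gate1DD01	10	112.7	OP, SC, HI, CT, FS	↓ leaf	Hypothetical protein	II
b	Cotton12_35202_01	G1099	10	116.2	OP, SC, HI, CT, FS	↓ leaf	Glutamyl tRNA amidotransferase, subunit A	II
b	Cotton12_02930_01	Gafb28K14	11	45.7	d13C	↑ leaf	4-Coumarate:CoA ligase	II′
b	Cotton12_06698_01	pAR01D04	11	54.4	d13C	↑ root	Proline-rich protein APG-like	II′
b	Cotton12_18985_01	Gate4BD10a	12	22.3	SC, HI, BW	↓ root, ↑ leaf	Hypothetical protein	II
b	Cotton12_18065_01	Unig22D08	12	38.8	FL	↓ root	Hypothetical protein	II
b	Cotton12_19658_01	W11	13	47.6	OP, SC, HI, Chl-a	↑ root	Hypothetical protein	II
c	Cotton12_27963_01					↑ leaf	Fiber protein Fb17 (Fragment)	II
c	Cotton12_23787_01					↑ leaf	Hypothetical protein At2g04690	II
c	Cotton12_07697_01					↓ leaf	Hypothetical protein At5g65650	II
c	Cotton12_26110_01					↓ leaf	Hypothetical protein F3L17.50	II
c	Cotton12_31394_01					↑ root	Hypothetical protein OJ1520_C09.39	II
c	Cotton12_34263_01					↑ leaf	Inner membrane metabolite transport protein	II
c	Cotton12_35169_01					↑ leaf	NAC-domain protein	II′
c	Cotton12_22936_01					↓ leaf	Putative flavonol 3-O-glucosyltransferase	II′
c	Cotton12_05870_01					↑ leaf	OSJNBa0086B14.2 protein	II
c	Cotton12_32869_01					↑ root	Q9XEU0_DATGL	II
c	Cotton12_30514_01					↑ leaf	Q9XI23_ARATH	II
c	Cotton12_38044_01					↑ leaf	Syringolide-induced protein 1-3-1B	II
d	Cotton12_18881_01	CMS14	1	88.6	OP		No Hit	II
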