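region_traits	chromosome	region_lo_cM	region_hi_cM	segment_id	gene_id	gene_function
d13C, FF	2	64.0	77.6	D05.99	AT1G23130	Defense response
OP, Chl-a	4	29.0	93.5	D03.92	AT1G09250	Regulation of transcription
OP, Chl-a	4	29.0	93.5	D06.26	AT1G31930	G-protein coupled receptor protein signaling pathway
OP, Chl-a	4	29.0	93.5	D08.54	AT3G21240	Response to UV, response to wounding
OP, Chl-a	4	29.0	93.5	D11.56	AT2G45070	Protein transporter activity
BW, DM, SC, HI	5	36.7	106.2	D05.114	AT1G77760	Response to light stimulus
BW, DM, SC, HI	5	36.7	106.2	D15.111	AT3G16940	Calmodulin binding, transcription regulator activity
BW, DM, SC, HI	5	36.7	106.2	D23.119	AT5G09800	Protein ubiquitination
BW, DM, SC, HI	5	36.7	106.2	D01.119	AT4G00720	Kinase activity
BW, DM, SC, HI	5	36.7	106.2	D01.121	AT1G23740	Zinc ion binding
BW, DM, SC, HI	5	36.7	106.2	D02.120	AT2G32250	Response to red or far red light, zinc ion binding
BW, DM, SC, HI	5	36.7	106.2	D10.124	AT2G17290	Abscisic acid mediated signaling, regulation of stomatal movement
BW, DM, SC, HI	5	36.7	106.2	D11.122	AT2G35890	Calmodulin-dependent protein kinase activity
BW, DM, SC, HI	5	36.7	106.2	D12.116	AT5G28000	Response to biotic stimulus, defense response
BW, DM, SC, HI	5	36.7	106.2	D12.121	AT3G05530	Calmodulin binding, ubiquitin-dependent protein catabolic process
BW, DM, SC, HI	5	36.7	106.2	DS07.115	AT5G23420	Regulation of transcription
BW, DM, SC, HI	5	36.7	106.2	DS07.115	AT5G23540	Ubiquitin-dependent protein catabolic process
FS	7	91.2	131.4	D01.150	AT1G03010	Response to light stimulus, signal transducer activity
FS	7	91.2	131.4	D11.66	AT2G37250	Nucleotide kinase activity
FS	7	91.2	131.4	D11.66	AT2G37710	Kinase activity
FS	7	91.2	131.4	D12.153	AT3G02940	Response to salicylic acid stimulus, regulation of transcription
FS	7	91.2	131.4	D23.149	AT5G64330	Signal transducer activity
FS	7	91.2	131.4	D23.33	AT5G65020	Calcium-dependent phospholipid binding
SC, HI, BW, OP	7	167.0	217.0	D02.67	AT2G31750	Abscisic acid glucosyltransferase activity
SC, HI, BW, OP	7	167.0	217.0	D03.143	AT1G12270	Response to stress
SC, HI, BW, OP	7	167.0	217.0	D09.70	AT5G41360	Response to UV-B
SC, HI, BW, OP	7	167.0	217.0	D09.70	AT5G42020	Response to heat
SC, HI, BW, OP	7	167.0	217.0	D15.164	AT4G14130	Xyloglucan endotransglycosylase-related protein
SC, HI, BW, OP	7	167.0	217.0	D15.164	AT3G23830	Response to osmotic stress, response to salt stress
SC, HI, BW, OP	7	167.0	217.0	DS02.34	AT3G26700	Kinase activity
SC, HI, BW, OP	7	167.0	217.0	DS02.69	AT3G26700	Kinase activity
Chl-a, Chl-b, d13C	8	44.9	52.3	D06.183	AT1G31930	G-protein coupled receptor protein signaling pathway
Chl-a, Chl-b, d13C	8	44.9	52.3	D06.29	AT1G32640	Response to desiccation, response to abscisic acid stimulus
Chl-a, Chl-b, d13C	8	44.9	52.3	D10.73	AT2G22800	Regulation of transcription, DNA-dependent
Chl-a, Chl-b, d13C	8	44.9	52.3	D21.17	AT5G47030	ATP synthesis coupled proton transport
OP, SC, CT, HI	10	77.5	122.2	D10.232	AT4G37930	Oxygen and reactive oxygen species metabolic process
OP, SC, CT, HI	10	77.5	122.2	D10.232	AT5G20720	Response to cold, calmodulin binding
OP, SC, CT, HI	10	77.5	122.2	D17.231	AT2G43220	Zinc ion binding
OP, SC, CT, HI	10	77.5	122.2	D07.243	AT4G09460	Response to abscisic acid stimulus, response to salt stress, response to ethylene stimulus
OP, SC, CT, HI	10	77.5	122.2	D11.165	AT3G61150	Regulation of transcription, DNA-dependent
BW, HI, SC	12	0.0	25.5	D10.175	AT4G37930	Oxygen and reactive oxygen species metabolic process
BW, HI, SC	12	0.0	25.5	D17.269	AT3G43810	Calcium-mediated signaling
HI, SC	13	42.6	50.7	D03.88	AT1G08810	Stomatal movement, response to water deprivation, abscisic acid stimulus, salt stress, salicylic acid stimulus
HI, SC	13	42.6	50.7	D12.292	AT5G18100	Oxygen and reactive oxygen species metabolic process copper, zinc superoxide dismutase activity
OP	13	131.5	149.7	D10.303	AT4G37930	Oxygen and reactive oxygen species metabolic process
OP	13	131.5	149.7	D10.303	AT4G38230	Calmodulin-dependent protein kinase activity
OP	13	131.5	149.7	D10.304	AT2G21510	Heat shock protein binding
OP	13	131.5	149.7	D11.187	AT2G37290	Regulation of Rab GTPase activity
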