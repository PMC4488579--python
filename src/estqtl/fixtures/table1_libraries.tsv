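library_id	tissue	treatment	n_ests
GH_ECOT	etiolated cotyledon	none	5084
GH_SDL	seedling	control	1378
GH_SDLD	seedling	drought	589
GH_SDCH	seedling	chilling	207
GH_FOX	ovary	none	6896
GH_MDI	boll_8_10dpa	control	946
GH_MDDS	boll_8_10dpa	drought	988
GH_LDI	boll_15_20dpa	control	1428
GH_LDDS	boll_15_20dpa	drought	1014
GH_STEM	stem	none	6588
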