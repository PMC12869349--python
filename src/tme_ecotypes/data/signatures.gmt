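cytotoxicity	curated T/NK cytotoxicity program	PRF1	IFNG	GNLY	NKG7	GZMA	GZMH	KLRK1	KLRB1	KLRD1	CTSW	CST7
exhaustion_inhibitory	curated T-cell exhaustion/inhibitory program	CXCL13	HAVCR2	PDCD1	TIGIT	LAG3	CTLA4	LAYN	RBPJ	VCAM1	TOX	MYO7A
MonoMacro_c2	marker_derived refined monocyte subset signature	INHBA	CCL20	IL1RN	SLC7A11	CXCL3	VEGFA
MonoMacro_c4	marker_derived refined macrophage subset signature	SPP1	TREM2
MonoMacro_c5c6	marker_derived refined macrophage subset signature	CXCL9	CXCL10	ANKRD22
MonoMacro_c8c9	marker_derived refined tissue-resident macrophage signature	FOLR2	SELENOP	SLC40A1
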