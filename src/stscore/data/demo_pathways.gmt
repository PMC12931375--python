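demo_type_i_ifn_response	synthetic demo set	IFIT1	USP18	MX1	IFI27	IFI44L	OAS1	ISG15	STAT1	IRF7	IFI6
demo_apoptosis	synthetic demo set	CASP3	CASP8	BAX	BAK1	CYCS	TP53	FAS	APAF1
demo_necroptosis	synthetic demo set	RIPK1	RIPK3	MLKL	ZBP1
demo_macrophage_activation	synthetic demo set	CD68	FCGR3A	FCGR1A	CD163	ARG1	IL1B	TNF	IL10
demo_tgfb_signaling	synthetic demo set	TGFB1	SMAD2	SMAD3	SMAD4	ACTA2	COL1A1	COL3A1
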