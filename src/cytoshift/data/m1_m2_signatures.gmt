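M1	classical (LPS+IFNg-induced) macrophage activation signature	ADAM28	AIM2	ANKRD22	APOBEC3A	APOL1	APOL3	BATF2	C1R	C1S	CCL19	CD38	CD40	CD80	CFB	CLEC4D	CXCL10	CXCL9	CYBB	DUCP10	DUSP6	ETV7	FAM49A	FAM65B	FCGR1B	FPR2	GADD45G	GBP1	GBP2	GBP4	GBP5	GCH1	GK	GPR84	GUCY1A3	HERC5	HESX1	HLA-F	IFI27	IFI35	IFI44L	IFIH1	IFIT2	IFIT3	IFITM1	IFITM2	IL15	IL15RA	IL32	INHBA	IRF1	IRF7	ISG15	ISG20	ITGAL	ITGB7	LAG3	LAMP3	LIMK2	LRRK2	MUC1	MX1	NAMPT	NFKBIZ	OAS1	OAS2	OAS3	OASL	OPTN	PAG1	PARP14	PCNX	PDE4B	PIM1	PRKAR2B	PSMB9	PTGS2	RARRES3	RCN1	RHBDF2	RSAD2	SAT1	SCO2	SEPT4	SERPING1	SLAMF7	SLC22A15	SLC25A28	SLC31A2	SLC6A12	SLC7A5	SNTB1	SNX10	SOCS3	SOD2	STAT1	STAT3	STX11	TAP1	TNFAIP6	TNFSF10	TRIM69	UBE2L6	USP18	VAMP5	WARS	XRN1
M2	alternative (IL-4/IL-13-induced) macrophage activation signature	ADAM19	ALOX15	ARRB1	BZW2	CARD9	CCL13	CCL17	CCL23	CD1A	CD1C	CD1E	CDR2L	CHN2	CLEC4A	CLIC2	CMTM8	CRIP1	CTSC	DUSP22	EMILIN2	ESPNL	F13A1	FOXQ1	FSCN1	FZD2	GALNTL4	GATM	GPD1L	GSTP1	ITM2C	KCNK6	MAOA	MAP4K1	MAPKAPK3	MFNG	MS4A6A	NMNAT3	OSBPL7	P2RY11	PALLD	PAQR4	PELP1	PLAU	PON2	PPP1R14A	PTGS1	RAMP1	REPS2	RGS18	RRS1	S100A4	SEC14L5	SHPK	SPINT2	TGFB1	TMEM97	VCL	SNF789
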