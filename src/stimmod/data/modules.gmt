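BAFF	TOP100 genes responding to BAFF stimulation of transformed GC B cells	ID1	ID4	BNIP3	TXNIP	BNIP3L	PFKFB4	GPER	PNOC	RGS18	P4HA1	CCNG2	HILPDA	ID2	SAMD13	CD24	ID3	C3orf37	GPR18	ALDOC	BBOX1	CD83	POLD4	HBP1	FAM167A	EVI2A	TP53INP1	YPEL5	TRIM22	TLR1	CLEC2B	HLA-C	ACTR3	NAF1	PSMD12	NUDT5	TESC	CCAR1	ANKRD33B	RILPL2	PLCB1	NFKBIE	DDX21	TAPBP	RBBP6	SOGA2	HINT1	SRRM1	PHACTR4	AK3	KPNB1	GTF2H2B	TAF1D	CSF2RB	MYBBP1A	YY1	FLVCR1	NAA16	SRRT	TNRC6A	FNBP1	CIZ1	TOMM40	TBC1D24	ILF3	NFKB2	TFDP1	ZNF385C	LYAR	BIRC3	LRP8	CCDC28B	C8orf12	HLA-B	HSP90B1	KLHDC5	RP9	PEA15	MT1X	MAN1A1	DNAJB1	SOGA1	CENPV	ICAM1	CD58	NCOR2	SNHG12	SLC23A2	OLFML2A	LRRFIP1	DENND4A	IGLL1	OVOS2	C1orf63	EIF5B	RUNX3	HLA-DQB1	HLA-DQA1	TCOF1	ELL2
CD40L	TOP100 genes responding to CD40L stimulation of transformed GC B cells	ID1	C3orf37	SMAD1	DEPTOR	CAB39L	CD83	METTL7A	ANKRD36BP2	ID3	ENPP3	IRF8	RGS18	FAM167A	AICDA	GPER	ID4	PDZRN4	BNIP3	VEGFA	TP53INP1	PTPRC	RASSF6	CCNG2	CLEC2B	BMP7	TLR1	SATB1	BTG2	PCDH9	PRKACB	GPM6A	STAT2	CLIP2	ARHGAP17	CFLAR	FYTTD1	HLA-DMB	MTMR10	HLA-F	PLEK	PPP1R9B	TESC	IGLL1	SNX20	CREM	IKBKE	FAS	CIITA	TAP1	NOTCH2NL	RFX5	FDXR	NFKBIE	MIR155HG	LOXL2	HLA-B	VAV2	ZNF385C	RASSF2	HLA-E	BIRC3	ANKRD33B	ANXA7	HVCN1	EPB41L4B	PIK3CD	LAT2	HCP5	HLA-DOA	SYNGR2	ALCAM	WNT5A	RUNX3	BMP2K	CTSH	PLEKHO1	RPS6KA1	DUSP22	IFIH1	OLFML2A	HLA-DQB1	COL1A1	ICAM1	NFKB2	NEIL2	FNBP1	BATF	CCDC28B	MAN1A1	CUX2	HLA-DQA1	DENND4A	HLA-DPA1	RILPL2	DOCK10	BTN2A2	ELL2	CD58	LINC00158
aIgM	TOP100 genes responding to aIgM stimulation of transformed GC B cells	CYP26A1	ID4	BEST3	IL7R	BMP7	SOX4	TNFSF8	RNF144B	DNAJB4	ID1	BCL6	RHOH	RGCC	NCKAP1	IKZF1	HEY2	PCDH9	SOX2	MYCT1	RGS18	SMAD1	MLLT3	KIF20A	FAM214A	BCL2	PSAT1	LOC285628	FAIM3	MAP2K3	PPP1R15A	FAM208B	SIAH2	HIVEP3	METRNL	HERPUD1	KLF10	LTA	GPR18	IFRD1	CD274	SLC3A2	HSPA5	ATF3	DENND4A	ARHGAP25	TOR3A	IRF2BP2	SLC30A1	TNF	CTH	APOBEC3B	NFKB1	CD58	NFKBIE	NAB2	JUND	ARL4C	UPP1	CDKN1A	FAM100B	MDFIC	IER2	DUSP10	FAM102A	RAB8B	PTGER4	HLA-DQB1	ARAP2	SLC7A11	MIR155HG	CD69	TSC22D3	RGS16	ZFP36L1	TRIB3	IL21R	KLF6	PHACTR1	SESN2	TNFAIP3	CD1C	PLEK	FAM46C	CD83	DDIT3	DUSP2	SQSTM1	PHLDA1	BHLHE40	SLAMF7	CCR7	LINC00158	LY9	EGR1	BCL2A1	EGR2	SGK1	DUSP5	RGS1
IL21	TOP100 genes responding to IL21 stimulation of transformed GC B cells	BCL6	SOX2	DNAJB4	ID3	DDIT4	ID1	RGCC	IL7R	HEY2	VEGFA	GADD45A	CYTIP	PCDH9	CCNG2	TXNIP	BICD2	RGS18	ANKRD37	TRIM8	KIAA0907	NEDD9	RELB	PAPD5	ZNFX1	B3GNT2	HIF1A	KIF26B	MMD	AICDA	EPSTI1	RAB11FIP1	RAB30	SIN3A	PLEK	IFITM1	PRDM2	DUSP10	FAM100B	FAS	IL7	CD69	B4GALT1	BCL2L1	CD40	TET3	SOCS1	NFKBID	SRSF5	MASTL	TLR7	MCL1	PIM2	IER2	ZFP36L1	IFIT2	SNX11	TAP1	JUNB	LRRC32	MARCKS	DUSP2	NUDT4	CXCR5	IER5	BCL3	SAMSN1	NFKBIZ	IL2RA	PARP9	USP18	MAP3K8	ZC3H12A	NFKBIA	RGS16	GADD45B	MIR155HG	LINC00158	PTGER4	DTX3L	CXCL10	TNFAIP3	MX1	STAT1	BIRC3	EGR2	NFKBIE	IFIT5	BCL2A1	IRF1	SLC30A1	IFIT3	IRF4	IFIT1	CMPK2	BATF	CD83	SGK1	ICAM1	IRF9
LPS	TOP100 genes responding to LPS stimulation of transformed GC B cells	ID1	RGS18	C3orf37	DDIT4	ID3	METTL7A	CAB39L	TXNIP	BNIP3	ID4	CCNG2	PFKFB4	KDM3A	HILPDA	FAM167A	PTPRC	STAT2	SAMD13	ENPP3	SMAD1	P4HA1	VEGFA	KLRC3	GPER	ZNF385B	TP53INP1	UBE2H	TRIM22	PIK3C2B	STAP1	BNIP3L	MYBL1	GPM6A	ANKRD37	SPG11	NARF	ABCA1	SEC14L1	IL7R	H1FX	ASF1A	GLCCI1	EVI2A	VGLL4	PRKACB	LRP4	PLCXD1	CLEC2B	LOC440864	SLC44A1	TSPAN11	BTN2A2	NFKBIE	HLA-C	LSS	FDXR	KLHDC5	HLA-B	CCDC28B	HLA-DMB	CUX2	DUSP22	RPS6KA1	HLA-DOA	SYNCRIP	ZNF385C	DENND4A	PDLIM3	FYTTD1	ELL2	HLA-E	IRF2BP2	DNAJB1	IGLL1	TFDP1	PSPC1	ANKRD33B	CREBZF	IRF4	C8orf12	FNBP1	ANXA7	MT1X	BATF	CALR	HLA-DQA1	OLFML2A	UMODL1	HLA-DQB1	IKBKE	NEIL2	RILPL2	MAN1A1	CREM	HLA-DPA1	ACTR3	CD58	LINC00158	IFIT3
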