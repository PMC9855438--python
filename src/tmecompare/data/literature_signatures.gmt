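naiveness	canonical naive T markers	TCF7	CCR7	SELL	LEF1
exhaustion_canonical	canonical T exhaustion checkpoints	PDCD1	CTLA4	LAG3	HAVCR2	TIGIT	TOX	ENTPD1
treg	regulatory T cell program	FOXP3	IL2RA	IKZF2	CTLA4	TNFRSF18	TNFRSF4	BATF
cytotoxicity	cytotoxic effector program	GZMA	GZMB	GZMH	GZMK	PRF1	NKG7	GNLY	IFNG	KLRD1
proliferation	cell-cycle program	MKI67	TOP2A	STMN1	PCNA	TYMS	MCM2	CCNB1	CDK1
m1_activation	classically activated macrophage	IL1B	TNF	CXCL9	CXCL10	CD80	CD86	IL6	NOS2	SOCS3
m2_activation	alternatively activated macrophage	MRC1	CD163	MSR1	IL10	CCL22	TGFB1	CD209	F13A1
angiogenesis	pro-angiogenic program	VEGFA	VWF	CDH5	FLT1	KDR	ANGPT2	TEK	PGF
phagocytosis	phagocytic program	MRC1	CD163	MERTK	C1QA	C1QB	C1QC	GULP1
dc_activation	dendritic cell activation	CD80	CD86	CD40	RELB	CD83	HLA-DQA1	FCER1A
dc_migration	dendritic cell migration	CCR7	FSCN1	LAMP3	CCL19	MYO1G	ADAM8
dc_tolerance	tolerogenic dendritic program	CD274	PDCD1LG2	IDO1	SOCS1	SOCS2	CD200	ALDH1A2
hla_class_i	HLA class I antigen presentation	HLA-A	HLA-B	HLA-C	B2M
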