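cytotoxicity	granzyme/perforin-mediated killing machinery	GZMA	GZMB	GZMH	PRF1	GNLY	CTSW	KLRB1	KLRD1	KLRK1	NKG7	FASLG	CD8A	CD8B
interferon_signaling	type I/II interferon response	IFNGR2	GBP1	GBP2	GBP4	IFIT3	OASL	JAK1	CXCL10	CXCL11	IFNG
cytokine_receptor_interaction	cytokine and cytokine-receptor genes	IL2	IL15	TSLP	CXCL10	CXCL11	CXCL16	CXCR4	FASLG	PRLR	TNFRSF4	TNFRSF1A	TNFSF12	CD70	CSF3R	CSF1R
antigen_presentation	MHC and antigen processing	HLA-A	HLA-B	HLA-C	TAP1	TAP2	B2M	PSMB8	PSMB9
b_cell_function	B-cell receptor programme	BLK	CD19	MS4A1	FAM30A	TNFRSF17	FCRL2	SPIB	PNOC
myeloid_compartment	macrophage / neutrophil / mast programmes	CD68	CD84	CD163	MS4A4A	FPR1	SIGLEC5	CSF3R	FCAR	FCGR3B	CEACAM3	S100A12	TPSAB1	TPSB2	CPA3	MS4A2	HDC
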