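# Marker-gene catalog for the 14 immune-cell populations scored by the pipeline.
# Each population score is the arithmetic mean of its markers' log2 normalized
# expression (Danaher-style relative abundance). Lists are editable data: pass
# an alternative YAML of the same shape to override.
#
# "CD56dim NK cells" uses KIR3DL1 and KIR3DL2 where only the truncated family
# name "KIR3DL" circulates in figure legends; see docs/methods.md.
populations:
  B cells: [BLK, CD19, FAM30A, MS4A1, TNFRSF17, FCRL2, SPIB, PNOC]
  CD45+ cells: [PTPRC]
  CD56dim NK cells: [KIR2DL3, KIR3DL1, KIR3DL2, IL21R]
  CD8+ T cells: [CD8A, CD8B]
  Cytotoxic cells: [PRF1, GZMA, GZMB, GZMH, GNLY, CTSW, KLRB1, KLRD1, KLRK1, NKG7]
  Dendritic cells: [CCL13, CD209, HSD11B1]
  Exhausted CD8+ T cells: [LAG3, CD244, EOMES, PTGER4]
  Macrophages: [CD68, CD84, CD163, MS4A4A]
  Mast cells: [TPSAB1, TPSB2, CPA3, MS4A2, HDC]
  Neutrophils: [FPR1, SIGLEC5, CSF3R, FCAR, FCGR3B, CEACAM3, S100A12]
  NK cells: [NCR1, XCL1, XCL2]
  T cells: [CD3D, CD3E, CD3G, CD6, SH2D1A, TRAT1]
  Th1 cells: [TBX21]
  Treg cells: [FOXP3]
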