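cell_type	gene_symbol
leukocytes	Ptprc
B_cells	Ms4a1
B_cells	Tnfrsf17
T_cells	Cd3d
T_cells	Cd3e
T_cells	Cd3g
T_cells	Cd6
T_cells	Sh2d1a
Th1_cells	Tbx21
Treg_cells	Foxp3
CD8_T_cells	Cd8a
CD8_T_cells	Cd8b1
exhausted_CD8_cells	Cd244
exhausted_CD8_cells	Eomes
exhausted_CD8_cells	Lag3
cytotoxic_cells	Ctsw
cytotoxic_cells	Gzma
cytotoxic_cells	Gzmb
cytotoxic_cells	Klrb1
cytotoxic_cells	Klrd1
cytotoxic_cells	Klrk1
cytotoxic_cells	Prf1
dendritic_cells	Ccl2
dendritic_cells	Cd209e
dendritic_cells	Hsd11b1
macrophages	Cd163
macrophages	Cd68
macrophages	Cd84
mast_cells	Ms4a2
neutrophils	Csf3r
neutrophils	Fcgr4
NK_cells	Ncr1
NK_cells	Xcl1
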