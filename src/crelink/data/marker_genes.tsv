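cell_type	gene
Epithelial	EPCAM
Epithelial	KRT19
Fibroblast	DCN
Fibroblast	COL1A1
Endothelial	PECAM1
Endothelial	CLDN5
Tcell	CD3D
Tcell	TRAC
NK	NKG7
NK	GNLY
Bcell	CD79A
Bcell	IGHM
Myeloid	LYZ
Myeloid	CD68
Mast	KIT
Mast	MS4A2
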