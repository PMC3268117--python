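list_name	gene_symbol
core_overlap_17	COL5A2
core_overlap_17	FAP
core_overlap_17	POSTN
core_overlap_17	COL1A2
core_overlap_17	COL3A1
core_overlap_17	FBN1
core_overlap_17	TNFAIP6
core_overlap_17	MMP2
core_overlap_17	GREM1
core_overlap_17	BGN
core_overlap_17	CDH11
core_overlap_17	SPOCK1
core_overlap_17	DCN
core_overlap_17	COPZ2
core_overlap_17	THY1
core_overlap_17	PCOLCE
core_overlap_17	PRRX1
validated_up_29	COL11A1
validated_up_29	THBS2
validated_up_29	COL5A2
validated_up_29	COL5A1
validated_up_29	VCAN
validated_up_29	COL1A1
validated_up_29	COL3A1
validated_up_29	FN1
validated_up_29	SULF1
validated_up_29	FBN1
validated_up_29	ASPN
validated_up_29	SPARC
validated_up_29	CTSK
validated_up_29	MMP2
validated_up_29	BGN
validated_up_29	LUM
validated_up_29	LOXL2
validated_up_29	COL6A3
validated_up_29	TIMP3
validated_up_29	CDH11
validated_up_29	SERPINF1
validated_up_29	EDNRA
validated_up_29	ACTA2
validated_up_29	PDGFRB
validated_up_29	SNAI2
validated_up_29	LGALS1
validated_up_29	GLT8D2
validated_up_29	NID2
validated_up_29	PRRX1
emt_tf_panel	SNAI1
emt_tf_panel	SNAI2
emt_tf_panel	TWIST1
emt_tf_panel	ZEB1
emt_tf_panel	ZEB2
emt_tf_panel	FOXC2
adipocyte_markers	ADIPOQ
adipocyte_markers	CFD
adipocyte_markers	FABP4
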