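amino_acid	aa_id	aa_formula	aa_charge	oxo_id	oxo_name	oxo_formula	oxo_charge
D-Alanine	ala__D	C3H7NO2	0	pyr	Pyruvate	C3H3O3	-1
D-Asparagine	asn__D	C4H8N2O3	0	2oxsucam	2-Oxosuccinamate	C4H4NO4	-1
D-Aspartate	asp__D	C4H6NO4	-1	oaa	Oxaloacetate	C4H2O5	-2
D-Glutamate	glu__D	C5H8NO4	-1	akg	2-Oxoglutarate	C5H4O5	-2
D-Lysine	lys__D	C6H15N2O2	1	6a2ohx	6-Amino-2-oxohexanoate	C6H11NO3	0
D-Serine	ser__D	C3H7NO3	0	hpyr	Hydroxypyruvate	C3H3O4	-1
D-Valine	val__D	C5H11NO2	0	3mob	3-Methyl-2-oxobutanoate	C5H7O3	-1
D-2-Aminobutyrate	2abut__D	C4H9NO2	0	2obut	2-Oxobutanoate	C4H5O3	-1
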