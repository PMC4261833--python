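compound	source_class	ec_number	gene_id	source	qc_status
Cysteamine-S-phosphate	phosphorus	3.1.3.1	JLM_162926	annotation_db	pass
Tetrathionate	sulfur	1.8.2.2		psi_blast	insignificant_evalue
Tetrathionate	sulfur	1.8.5.2		psi_blast	insignificant_evalue
D-Alanine	nitrogen	1.4.1.1	XP_001700222.1	psi_blast	pass
D-Alanine	nitrogen	1.5.1.22		psi_blast	failed_manual_qc
D-Alanine	nitrogen	2.1.2.7		psi_blast	insignificant_evalue
D-Alanine	nitrogen	1.4.3.3	Cre02.g096350.t1.3	annotation_db	pass
D-Alanine	nitrogen	2.3.2.10		psi_blast	insignificant_evalue
D-Alanine	nitrogen	2.3.2.14		psi_blast	insignificant_evalue
D-Alanine	nitrogen	2.3.2.16		psi_blast	insignificant_evalue
D-Alanine	nitrogen	2.3.2.17		psi_blast	insignificant_evalue
D-Alanine	nitrogen	2.3.2.18		psi_blast	insignificant_evalue
D-Alanine	nitrogen	2.6.1.21		psi_blast	failed_manual_qc
D-Alanine	nitrogen	3.4.13.22	XP_001698572.1	psi_blast	pass
D-Alanine	nitrogen	3.4.13.22	XP_001693532.1	psi_blast	pass
D-Alanine	nitrogen	3.4.13.22	XP_001701890.1	psi_blast	pass
D-Alanine	nitrogen	3.4.13.22	XP_001700930.1	psi_blast	pass
D-Alanine	nitrogen	3.4.16.4	Chlre2_kg.scaffold_14000039	annotation_db	pass
D-Alanine	nitrogen	3.4.17.8		psi_blast	failed_manual_qc
D-Alanine	nitrogen	3.4.17.13		psi_blast	insignificant_evalue
D-Alanine	nitrogen	3.4.17.14		psi_blast	insignificant_evalue
D-Alanine	nitrogen	4.5.1.2		psi_blast	insignificant_evalue
D-Alanine	nitrogen	6.1.1.13		psi_blast	failed_manual_qc
D-Alanine	nitrogen	6.1.2.1		psi_blast	failed_manual_qc
D-Alanine	nitrogen	6.3.2.4	au.g14655_t1	annotation_db	pass
D-Alanine	nitrogen	6.3.2.10		psi_blast	failed_manual_qc
D-Alanine	nitrogen	6.3.2.16		psi_blast	insignificant_evalue
D-Alanine	nitrogen	6.3.2.35		psi_blast	insignificant_evalue
D-Asparagine	nitrogen	1.4.5.1		psi_blast	insignificant_evalue
D-Asparagine	nitrogen	1.4.3.3	Cre02.g096350.t1.3	annotation_db	pass
D-Asparagine	nitrogen	3.1.1.96		psi_blast	insignificant_evalue
D-Asparagine	nitrogen	2.3.1.36		psi_blast	insignificant_evalue
D-Asparagine	nitrogen	1.4.99.1	XP_001692123.1	psi_blast	pass
D-Asparagine	nitrogen	3.5.1.77	e_gwW.1.243.1	annotation_db	pass
D-Asparagine	nitrogen	3.5.1.81		psi_blast	insignificant_evalue
D-Asparagine	nitrogen	5.1.1.10		psi_blast	failed_manual_qc
D-Aspartic acid	nitrogen	6.3.1.12		psi_blast	insignificant_evalue
D-Aspartic acid	nitrogen	1.4.3.3	Cre02.g096350.t1.3	annotation_db	pass
D-Glutamic acid	nitrogen	1.4.3.7		psi_blast	insignificant_evalue
D-Glutamic acid	nitrogen	1.4.3.3		psi_blast	insignificant_evalue
D-Lysine	nitrogen	5.4.3.4		psi_blast	insignificant_evalue
D-Lysine	nitrogen	1.4.3.3	Cre02.g096350.t1.3	annotation_db	pass
D-Lysine	nitrogen	6.3.2.37		psi_blast	failed_manual_qc
D-Serine	nitrogen	2.7.11.8		psi_blast	insignificant_evalue
D-Serine	nitrogen	2.7.11.17	Cre12.g486350.t1.3	annotation_db	pass
D-Serine	nitrogen	3.4.21.78		psi_blast	failed_manual_qc
D-Serine	nitrogen	3.4.21.104		psi_blast	failed_manual_qc
D-Serine	nitrogen	4.3.1.18	g6244.t1	annotation_db	pass
D-Serine	nitrogen	4.3.1.18		psi_blast	failed_manual_qc
D-Serine	nitrogen	6.3.2.35		psi_blast	insignificant_evalue
D-Serine	nitrogen	6.3.3.5		psi_blast	insignificant_evalue
D-Serine	nitrogen	1.4.3.3	Cre02.g096350.t1.3	annotation_db	pass
D-Valine	nitrogen	1.21.3.1		psi_blast	failed_manual_qc
D-Valine	nitrogen	6.3.2.26		psi_blast	failed_manual_qc
D-Valine	nitrogen	1.4.3.3	Cre02.g096350.t1.3	annotation_db	pass
L-Pyroglutamic acid	nitrogen			none	no_evidence
Thiophosphate	phosphorus			none	no_evidence
Dithiophosphate	phosphorus			none	no_evidence
Ethylamine	nitrogen	6.3.1.6		none	no_evidence
D,L-alpha-Amino-butyric acid	nitrogen	2.1.1.49		psi_blast	insignificant_evalue
D,L-alpha-Amino-butyric acid	nitrogen	1.4.3.3	Cre02.g096350.t1.3	annotation_db	pass
Dipeptide	dipeptide	3.4.13.18	Cre02.g078650.t1.3	annotation_db	pass
Tripeptide	tripeptide	3.4.11.4	Cre16.g675350.t1.3	annotation_db	pass
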