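ID	MET-1	ASP-26	LEU-19	VAL-30	LYS-29	ASP-22	LEU-33	LYS-17	CYS-18	GLU-21	CooperativityScore
Snu66_peptide	2	6	1	6	2	4	1	0	1	1	8.35
Peptide-1	5	2	4	1	0	1	3	0	1	0	6.09
Peptide-2	2	2	4	2	1	2	1	1	3	0	6.79
Peptide-3	1	3	0	3	3	2	2	6	2	1	5.41
Peptide-4	0	6	4	4	3	2	6	0	0	1	8.15
Peptide-5	2	1	4	4	1	2	2	0	1	3	7.96
Peptide-6	5	5	1	2	2	3	1	2	3	1	9.35
Peptide-7	0	2	4	0	2	6	1	0	1	1	3.33
Peptide-8	2	5	2	4	4	2	2	1	1	2	5.85
Peptide-9	0	3	0	5	3	3	3	1	2	0	6.04
Peptide-10	0	0	0	5	2	2	1	0	1	0	4.42
Peptide-11	1	3	0	2	0	3	3	0	0	0	2.50
Peptide-12	0	0	2	2	3	2	3	0	0	0	5.18
Peptide-13	0	1	0	2	4	2	1	0	2	0	5.56
Peptide-14	0	3	0	2	0	3	2	2	1	0	0.68
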