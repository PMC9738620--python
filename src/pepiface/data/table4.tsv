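ID	Length	CA_Medoid	CA_Filtered	CA_Lowest	AA_Medoid	AA_Filtered	AA_Lowest
Peptide-1	17	1.28	1.04	0.94	1.23	1.00	0.92
Peptide-2	16	1.04	0.90	0.94	0.95	0.75	0.78
Peptide-3	15	1.57	1.16	0.97	1.43	1.07	0.92
Peptide-4	14	1.29	1.23	1.03	1.16	1.13	0.88
Peptide-5	13	1.61	1.09	1.11	1.41	0.97	1.17
Peptide-6	12	1.53	1.17	1.03	1.46	1.27	0.90
Peptide-7	11	1.28	1.08	0.97	1.44	1.18	0.99
Peptide-8	10	1.50	1.16	1.03	1.34	1.20	0.92
Peptide-9	9	1.23	1.12	0.65	1.48	1.01	0.71
Peptide-10	8	2.07	1.00	0.84	2.08	0.89	0.84
Peptide-11	7	1.40	0.93	0.95	1.45	1.00	0.96
Peptide-12	6	0.92	0.57	0.86	0.94	0.88	0.76
Peptide-13	5	0.98	0.86	0.71	1.31	0.97	0.79
Peptide-14	10	1.57	0.84	0.90	1.50	0.89	0.88
Snu-66 peptide	18	1.95	1.24	1.09	1.70	1.09	1.00
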