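ID	Sequence	Length
Snu66 peptide	LSIEETNEIREKLGMKPI	18
Peptide-1	SIEETNEIREKLGMKPI	17
Peptide-2	IEETNEIREKLGMKPI	16
Peptide-3	EETNEIREKLGMKPI	15
Peptide-4	ETNEIREKLGMKPI	14
Peptide-5	TNEIREKLGMKPI	13
Peptide-6	NEIREKLGMKPI	12
Peptide-7	EIREKLGMKPI	11
Peptide-8	IREKLGMKPI	10
Peptide-9	IREKLGMKP	9
Peptide-10	IREKLGMK	8
Peptide-11	IREKLGM	7
Peptide-12	IREKLG	6
Peptide-13	IREKL	5
Peptide-14	TNEIREKLGM	10
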