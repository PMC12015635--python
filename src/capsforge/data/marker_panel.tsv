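locus	snp_id	primer_f_id	primer_f	primer_r_id	primer_r	annealing_c	size	enzyme	digest_allele	size_up	size_down
1	1_14411896_T_C	AL1-144F	CGTTCAAAAGCGTGTCCTGTG	AL1-144R	AGATTCCGTCTTGGATCATGGG	57.3	642	MnlI	C	200	442
2	1_26305924_A_G	AL1-263F	GCTGTGATCTGCACGTTTTTG	AL1-263R	TTGAGTTTGGACTGCCTTGGT	58.5	807	BstCI	G	584	223
3	1_28476668_A_G	AL1-284F	ATGAGTTTGGTAAGCCTGACG	AL1-284R	TTGTAAACCTTCGCAAAGCCC	62.0	701	Hpy99I	G	187	718
4	1_3626953_G_A	AL1-362F	TCACCAATCACCATCGTTGAGA	AL1-362R	TGTGTTATACTGGTTCCAAACTCT	62.5	768	AflIII	G	251	517
5	3_3650730_C_G	AL3-365F	TGATGCGAGAAGTTGCTGTG	AL3-365R	TCTGGCTCGTCAATTCCCTG	57.2	675	DdeI	C	234	441
6	4_16377278_G_T	AL4-163F	CTGGCAGAGTTGTTCGACGG	AL4-163R	GGTATGCTTCACTACACATCCG	64.2	752	NdeI	T	479	273
7	4_18833063_C_T	AL4-188_2F	CGTATGCACCGCAAAAAGTACG	AL4-188_2R	TACGCGAAGACGCGGAAAC	55.2	577	MseI	T	284	293
8	4_3731694_G_A	AL4-373F	TGCTGAAACAAGGGAACTATCTGA	AL4-373R	TCACTTCTTGCTGGTGCCAA	60.3	680	SmlI	A	451	229
9	5_16930178_G_A	AL5-169F	CTGAGAGTGAGTCCACCAGT	AL5-169R	TCCAAGTCAAATGGCTACCTC	59.0	860	Bsu36I	A	557	303
10	5_21025941_A_G	AL5-210F	TGAGGTTTCTGGTTAGGATGGG	AL5-210R	CAGTTTGCAGTAACATGTGAAAACG	62.0	694	BclI-HF	A	463	231
11	6_7579614_C_T	AL6-757F	CTCCCATGGGGCAGATGACT	AL6-757R	AGCCTTGGTACTCATGAAAGTGT	51.0	789	NsiI-HF	C	207	582
12	6_8478467_T_A	AL6-847F	CACGAGCAAAGTGCGTGTTC	AL6-847R	GAGAGACGGTGGAGATACCG	63.0	798	AseI	A	292	506
13	7_5932531_C_T	AL7-593F	ACTGGTCGATATGCTGCTGT	AL7-593R	GAGCTTTGTTCACCCTTGCG	59.5	579	MwoI	C	326	253
14	7_7632091_T_C	AL7-763F	AGGCCGGAATACCTCCTAGC	AL7-763R	CGTCCGGATCAGTTTCCCAT	55.4	646	NsiI	T	205	441
15	7_780813_C_T	AL7-780F	ACGGTAAGCAATATTAGTTTTTCCA	AL7-780R	TGAAGGAAAGAGCAATGGGT	54.2	650	SacII	C	406	244
16	8_14466046_C_T	AL8-144F	GTTCTTCACAGCTTCTATGCTTCA	AL8-144R	GGAACTTCAGCTGCTAAGGA	60.5	741	MspI	C	224	517
17	8_3829008_A_G	AL8-382F	GAGGTGACTACAGGCCAAGA	AL8-382R	CTGAAGGCCACTGGGGAATAGA	58.0	806	CviQI	G	498	308
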