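name	recognition	cut_top	cut_bottom	source
MnlI	CCTC	11	10	REBASE CCTC(7/6)
BstCI	GGCC	2	2	REBASE GG^CC (HaeIII isoschizomer; least-documented entry, see docs)
Hpy99I	CGWCG	5	0	REBASE CGWCG^
AflIII	ACRYGT	1	5	REBASE A^CRYGT
DdeI	CTNAG	1	4	REBASE C^TNAG
NdeI	CATATG	2	4	REBASE CA^TATG
MseI	TTAA	1	3	REBASE T^TAA
SmlI	CTYRAG	1	5	REBASE C^TYRAG
Bsu36I	CCTNAGG	2	5	REBASE CC^TNAGG
BclI-HF	TGATCA	1	5	REBASE T^GATCA (BclI recognition; HF = NEB high-fidelity variant)
NsiI-HF	ATGCAT	5	1	REBASE ATGCA^T (NsiI recognition; HF = NEB high-fidelity variant)
AseI	ATTAAT	2	4	REBASE AT^TAAT
MwoI	GCNNNNNNNGC	7	4	REBASE GCNNNNN^NNGC
NsiI	ATGCAT	5	1	REBASE ATGCA^T
SacII	CCGCGG	4	2	REBASE CCGC^GG
MspI	CCGG	1	3	REBASE C^CGG
CviQI	GTAC	1	3	REBASE G^TAC
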