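locus	maf_target_pop	ref_allele	minor_allele	maf_other_pops	minor_allele_other	n_polymorphic_pop
1	0.45	T	T	0.02	C	1
2	0.40	A	A	0.35	G	5
3	0.25	A	A
4	0.47	G	A
5	0.45	C	G
6	0.50	G	G/T
7	0.32	C	T
8	0.17	G	G
9	0.40	G	A	0.47	A	4
10	0.30	A	G
11	0.35	C	T	0.02	C	1
12	0.47	T	A
13	0.45	C	C
14	0.32	T	T
15	0.50	C	C/T	0.20	C	2
16	0.50	C	C/T
17	0.45	A	G	0.15	G	1
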