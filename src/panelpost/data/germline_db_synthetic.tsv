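# Synthetic offline population/database fixture (not real dbSNP/COSMIC data).
# pop_freq: population allele frequency; dbsnp/cosmic: 0/1 membership flags.
chrom	pos	ref	alt	pop_freq	dbsnp	cosmic
chr4	2000150	A	T	0.25	1	0
chr4	3000210	T	A	0.11	1	0
chr17	1000120	G	C	0.62	1	0
chr12	1000180	C	G	0.09	1	0
chr11	2000140	T	C	0.005	1	0
chr12	2000160	G	T	0.0	0	1
chr7	3000130	T	G	0.0	0	1
chr14	1000150	G	A	0.0005	1	1
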