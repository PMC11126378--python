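##fileformat=VCFv4.2
##contig=<ID=1,length=248956422>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	DDRD_P02	DDRD_P03	DDRD_P04	DDRD_P06	DDRD_P07
1	21770100	.	A	G	.	.	.	GT	0/0	0/0	0/0	0/0	0/0
1	21773254	.	C	T	.	.	.	GT	0/1	0/0	0/0	0/0	0/0
1	21774500	.	G	A	.	.	.	GT	0/0	./.	./.	./.	./.
1	21775527	.	T	C	.	.	.	GT	1/1	1/1	0/1	0/1	0/1
1	21780000	.	A	G	.	.	.	GT	1/1	./.	0/1	./.	0/1
1	21790000	.	C	T	.	.	.	GT	0/0	0/0	0/1	0/0	0/0
1	21800000	.	G	A	.	.	.	GT	1/1	1/1	1/1	0/1	0/1
1	21810000	.	T	C	.	.	.	GT	./.	./.	./.	./.	./.
1	21820000	.	T	TACACAC	.	.	.	GT	1/1	1/1	0/1	0/1	0/1
1	21839005	rs1294413650	G	A	.	.	.	GT	1/1	1/1	0/1	0/1	0/1
1	21850000	.	C	T	.	.	.	GT	1/1	1/1	0/1	0/1	0/1
1	21861499	.	A	G	.	.	.	GT	1/1	1/1	0/1	0/1	0/1
1	21862954	.	G	A	.	.	.	GT	1/1	1/1	0/1	0/0	0/1
1	21865000	.	T	G	.	.	.	GT	0/1	0/0	0/0	0/0	0/0
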