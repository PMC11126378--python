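disease	coordinate_grch38	hgvs_c	hgvs_p	consequence	codon	domain_label	inmerf	cadd	dann	dbsnp	patient	zygosity_label
DDRD	21839005	c.9970G>A	p.G3324R	MISSENSE	3324	18th immunoglobulin-like region/Domain IV	0.752	0.927	0.989	rs1294413650	DDRD_P02	Hom
DDRD	21839005	c.9970G>A	p.G3324R	MISSENSE	3324	18th immunoglobulin-like region/Domain IV	0.752	0.927	0.989	rs1294413650	DDRD_P03	Hom
DDRD	21839005	c.9970G>A	p.G3324R	MISSENSE	3324	18th immunoglobulin-like region/Domain IV	0.752	0.927	0.989	rs1294413650	DDRD_P04	C. het
DDRD	21851790	c.7006+1G>A		SPLICING						rs778653296	DDRD_P04	C. het
DDRD	21839005	c.9970G>A	p.G3324R	MISSENSE	3324	18th immunoglobulin-like region/Domain IV	0.752	0.927	0.989	rs1294413650	DDRD_P06	C. het
DDRD	21889996	c.559C>T	p.R187X	NONSENSE	187					rs1332584154	DDRD_P06	C. het
DDRD	21839005	c.9970G>A	p.G3324R	MISSENSE	3324	18th immunoglobulin-like region/Domain IV	0.752	0.927	0.989	rs1294413650	DDRD_P07	C. het
DDRD	21831213	c.11562+2T>G		SPLICING							DDRD_P07	C. het
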