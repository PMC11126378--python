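disease	coordinate_grch38	hgvs_c	hgvs_p	consequence	codon	domain_label	inmerf	cadd	dann	dbsnp
SJS	21889500	c.574+481C>T		SPLICING						rs916959204
SJS	21887966-21887976	c.665_675del		FRAMESHIFT						
SJS	21884528-21887623	c.720_1654del		FRAMESHIFT						
SJS	21885405	c.1125C>G	p.C375W	MISSENSE	375	4th LDL receptor type A/Domain II	0.965	0.382	0.377	rs543805444
SJS	21884877	c.1356-10G>A		SPLICING						
SJS	21884513	c.1654+15G>A		SPLICING						rs886046043
SJS	21876592	c.2746C>T	p.R916X	NONSENSE	916					
SJS	21876497	c.2826+15G>A		SPLICING						
SJS	21875990	c.3056C>T	p.P1019L	MISSENSE	1019	2nd laminin type B/Domain III	0.595	0.319	0.599	rs62642528
SJS	21875668	c.3263T>C	p.L1088P	MISSENSE	1088	2nd laminin type B/Domain III	0.335	0.626	0.931	
SJS	21872996	c.3888+1G>A		SPLICING						
SJS	21865037	c.4432C>T	p.R1478C	MISSENSE	1478	3rd laminin type B/Domain III	0.515	0.593	0.992	rs1198712778
SJS	21864994-21864996	c.4473_4475del		INFRAME						
SJS	21864874	c.4595G>A	p.C1532Y	MISSENSE	1532	Interface between 3rd laminin type B and 7th laminin EGF-like/Domain III	0.966	0.647	0.749	rs137853248
SJS	21864192	c.4648C>T	p.R1550C	MISSENSE	1550	Interface between 3rd laminin type B and 7th laminin EGF-like/Domain III	0.741	0.705	0.997	rs1317669197
SJS	21864100	c.4740G>A		SPLICING						
SJS	21864095	c.4740+5G>A		SPLICING						rs886039909
SJS	21862125	c.4741-10T>G		SPLICING						
SJS	21855680	c.5702-5G>A		SPLICING						rs2290498
SJS	21854720	c.6179delC		FRAMESHIFT						
SJS	21851790	c.7006+1G>A		SPLICING						rs778653296
SJS	21850359	c.7294+4A>G		SPLICING						
SJS	21847842	c.7874-2A>G		SPLICING						rs931293134
SJS	21847960-21847840	Fusion of exons 60 and 61		SPLICING						
SJS	21846108	c.8464G>A		SPLICING						rs748523693
SJS	21846104	c.8464+4A>G		SPLICING						rs1572204991
SJS	21843375	c.8680C>T	p.Q2894X	NONSENSE	2894					rs1004543320
SJS	21842916-21842924	c.8759-3_8764del		INFRAME						
SJS	21842892	c.8788G>A	p.E2930K	MISSENSE	2930	Interface between 13th and 14th immunoglobulin-like regions/Domain IV	0.286	0.618	0.962	rs368020528
SJS	21842014	c.9181C>T	p.Q3061X	NONSENSE	3061					
SJS	21841541	c.9326delA		FRAMESHIFT						rs2098048505
SJS	21839888	c.9643delC		FRAMESHIFT						
SJS	21836803	c.10354C>T	p.R3452X	NONSENSE	3452					rs1208167285
SJS	21836802	c.10355G>A	p.R3452Q	MISSENSE	3452	19th immunoglobulin-like region/Domain IV	0.428	0.711	0.989	rs1327754652
SJS	21833870	c.10776delT		FRAMESHIFT						
SJS	21833381	c.10982G>A	p.R3661Q	MISSENSE	3661	Interface between 21st immunoglobulin-like region and 1st laminin type G/Domains IV and V	0.489	0.520	0.988	
SJS	21833363	c.11000C>T	p.T3667M	MISSENSE	3667	1st laminin type G/Domain V	0.571	0.943	0.968	rs369084217
SJS	21832510	c.11192delG		FRAMESHIFT						
SJS	21832495	c.11207G>A	p.R3736Q	MISSENSE	3736	1st laminin type G/Domain V	0.690	0.800	0.997	rs984839674
SJS	21831803	c.11208-7G>A		SPLICING						
SJS	21829582-21829583	c.11792dupC		FRAMESHIFT						
SJS	21828878	c.12194delC		FRAMESHIFT						
SJS	21824120	c.12899+1G>A		SPLICING						
SJS	21816592-21823699	c.12920del7108		SPLICING						
DDSH	21887995	c.646G>T	p.E216X	NONSENSE	216					
DDSH	21873006-21873009	c.3876_3879del		FRAMESHIFT						
DDSH	21872619	c.4029+1G>A		SPLICING						rs779249304
DDSH	21855589	c.5788C>T	p.Q1930X	NONSENSE	1930					
DDSH	21851786	c.7006+5G>A		SPLICING						rs1208832174
DDSH	21839005	c.9970G>A	p.G3324R	MISSENSE	3324	18th immunoglobulin-like region/Domain IV	0.752	0.927	0.989	rs1294413650
DDSH	21833551	c.10894C>T	p.R3632X	NONSENSE	3632					rs762281715
DDSH	21824603-21824604	c.12666-2_12677dup		FRAMESHIFT						
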