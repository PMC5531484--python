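patient_id	diagnosis	gene	cdna_change	protein_change	mutation_type	consequence	zygosity	read_depth	mosaic_fraction	maf_1000g	maf_esp6500	maf_exac	region_label	in_capture_vip1
1	SAVI	TMEM173	463G>A	V155M	SNV	missense	het	250						1
2	FHL2	PRF1	1034C>G	P345R	SNV	missense	het	250						1
2	FHL2	PRF1	c.50delT	L17fs	small_indel	frameshift	het	218		0.0008	0.001			1
3	FHL3	UNC13D	1090delC	S363RfsX1	small_indel	frameshift	het	210						1
3	FHL3	UNC13D	c.118-308C>T		SNV	intronic	het	99		0.28				0
4	FHL3	UNC13D	c.2831-13G>A		splice	splice_site	het	242						1
4	FHL3	UNC13D	2436_2437insTTGA	N813delinsLN	small_indel	inframe_indel	het	236						1
5	XLP1	SH2D1A	gene deletion		gene_deletion		n/a						whole_gene	1
6	ALPS	CASP10	A1216T	I406L	SNV	missense	het	250		0.0048	0.0026	0.0049		1
7	FHL5	STXBP2	c.1247-1G>C		splice	splice_site	hom	230			0.0002	0.0003		1
8	FHL2	PRF1	c.C272T	A91V	SNV	missense	het	227		0.02	0.034	0.0311		1
9	Familial SLE	PRKCD	c.G1294T	G432W	SNV	missense	hom	250						1
10	FHL4	STX11	gene deletion		gene_deletion		n/a						whole_gene	1
11	DADA2	CECR1	C752T	P251L	SNV	missense	het	177		0.0002	0.0001	0.00003		1
11	DADA2	CECR1	-12233delC	n/a	regulatory	UTR	het	247		0.07				1
12	DADA2	CECR1	c.T2C	M1T	SNV	missense	het	248				0.00002		1
12	DADA2	CECR1	c.144delG	G48fs	small_indel	frameshift	het	246				0.0002		1
13	XLP1	SH2D1A	exon 2 deletion		exon_deletion		n/a						exon 2	1
14	TRAPS	TNFRSF1A	255_278del	85_93del	small_indel	inframe_indel	het	163	0.07					1
15	CAPS	NLRP3	C1698A	F566L	SNV	missense	het	243	0.20					1
16	CAPS	NLRP3	G1699A	E567K	SNV	missense	het	426	0.03					1
17	AGS	TREX1	c.859_876del	287_292del	small_indel	inframe_indel	hom	233						1
18	PAPA	PSTPIP1	c.G748A	E250K	SNV	missense	het	298						1
19	CAPS	NLRP3	c.G2336T	G779V	SNV	missense	het	151						1
20	Amyloidosis	TTR	delGAinsTT	E74L	small_indel	inframe_indel	het	286						1
21	Blau	NOD2	G1534T	D512Y	SNV	missense	het	249						1
22	ALPS	FAS	569-2A>C		splice	splice_site	het	55						1
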