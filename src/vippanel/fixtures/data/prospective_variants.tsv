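patient_id	sex	gene	cdna_change	protein_change	consequence	predictions	zygosity	maf_1000g	maf_esp6500	maf_exac	published_pathogenic_ref	low_penetrance_whitelisted	phenotype_concordant	evidence_codes	printed_class
23	M	C5	715G>A	G239S	missense	B/T/N	het				0	0	0		3
23	M	CBS	833T>C	I278T	missense	P/D/A	het				0	0	0		3
23	M	PLCG2	1565C>G	P522R	missense	B/T/N	het				0	0	0		3
23	M	PTEN	650T>A	V217D	missense	D/D/D	het				1	0	1	S	5
23	M	TGFBR1	51_59del:GGCGGCGGC	17_20del	inframe_indel	-/-/-	het				0	0	0		3
23	M	TGFBR2	449delA	E150fs	frameshift	-/-/-	het				0	0	0		3
23	M	TRAP1	1946C>T	A649V	missense	B/T/N	het				0	0	0		3
24	F	CASP8	1415A>G	K472R	missense	D/D/D	het				0	0	0		3
24	F	COL4A1	1246C>G	P416A	missense	P/T/D	het				0	0	0		3
24	F	CTC1	26C>A	P9H	missense	B/D/N	het				0	0	0		3
24	F	LYST	9017A>G	K3006R	missense	B/T/D	het				0	0	0		3
24	F	NCF1	269G>A	R90H	missense	B/D/D	het				0	0	0		3
24	F	NOTCH3	509A>G	H170R	missense	P/T/D	het				0	0	0		3
24	F	STXBP2	503A>G	Q168R	missense	B/T/N	het				0	0	0		3
24	F	TNFAIP3	811C>T	R271X	nonsense	T/-/D	het				1	0	1	VS+S	5
25	M	C5	1060C>A	L354M	missense	D/D/D	het				0	0	0		3
25	M	NCF1	269G>A	R90H	missense	B/D/D	het				0	0	0		3
25	M	RNF213	12037G>A	D4013N	missense	D/T/N	het				1	0	1	S	5
25	M	TGFBR1	51_59del:GGCGGCGGC	17_20del	inframe_indel	-/-/-	het				0	0	0		3
25	M	WAS	995T>C	V332A	missense	B/T/N	hom				0	0	0		3
26	F	NCF1	292T>G	C98G	missense	D/D/D	het				0	0	0		3
26	F	NLRP12	2188dupG	V730fs	frameshift	-/-/-	het				0	0	0		3
26	F	TGFBR2	449delA	E150fs	frameshift	-/-/-	het				0	0	0		3
26	F	TTC37	4187A>G	N1396S	missense	B/T/D	het				0	0	0		3
26	F	UNC13D	2896C>T	R966W	missense	D/T/D	het				1	0	1	S	5
27	F	DNASE1	358_360del:GAT	120_120del	inframe_indel	-/-/-	het				0	0	0		3
27	F	DOCK8	2666C>T	A889V	missense	B/T/D	het				0	0	0		3
27	F	FASLG	280T>G	L94V	missense	D/D/D	het				0	0	0		3
27	F	NCF1	269G>A	R90H	missense	P/D/D	het				0	0	0		3
27	F	TGFBR2	449delA	E150fs	frameshift	-/-/-	het				0	0	0		3
27	F	UNC13D	2896C>T	R966W	missense	D/T/D	het				1	0	1	S	5
28	F	C7	1912G>A	D638N	missense	B/T/N	het				0	0	0		3
28	F	CTC1	2497G>C	D833H	missense	P/T/N	het				0	0	0		3
28	F	NCF1	269G>A	R90H	missense	P/D/D	het				0	0	0		3
28	F	PLOD1	1675C>T	R559C	missense	B/D/D	het				0	0	0		3
28	F	TRAP1	1406G>A	R469H	missense	D/D/D	het				0	0	0		3
28	F	WAS	391G>A	E131K	missense	D/D/D	het				1	0	1	VS+S	5
29	F	LPIN2	1876C>T	P626S	missense	B/T/N	het				0	0	1	S	4
29	F	LPIN2	608C>T	S203F	missense	P/T/D	het				0	0	1	S	4
29	F	PTEN	236C>T	A79V	missense	-/-/-	het				0	0	0		3
29	F	FAS	A136A>C	T46P	missense	D/T/N	het				0	0	0		3
30	F	C6	2087A>G	D696G	missense	B/T/D	het				0	0	0		3
30	F	CASP10	295A>G	K99E	missense	B/D/N	het				0	0	1	S	4
30	F	CFP	391C>G	Q131E	missense	B/T/N	het				0	0	0		3
30	F	LPIN2	1876C>T	P626S	missense	B/T/N	het				0	0	1	S	4
31	M	CFHR5	480dupA	P160fs	frameshift	-/-/-	het				0	0	0		3
31	M	CFHR5	622T>C	C208R	missense	D/D/N	het				0	0	0		3
31	M	HPS6	698T>G	L233R	missense	B/T/N	het				0	0	0		3
31	M	NCF1	269G>A	R90H	missense	B/D/D	het				0	0	0		3
31	M	NOTCH3	3130G>A	A1044T	missense	D/D/D	het				0	0	0		3
31	M	PLCG2	1444T>C	Y482H	missense	D/T/D	het				0	0	1	S	4
31	M	PLCG2	1712A>G	N571S	missense	B/D/D	het				0	0	1	S	4
31	M	TGFBR2	449delA	E150fs	frameshift	-/-/-	het				0	0	0		3
31	M	TRAP1	1728G>C	E576D	missense	B/T/D	het				0	0	0		3
32	M	CBS	T833T>C	I278T	missense	P/D/A	het				0	0	0		3
32	M	LYN	1523A>T	Y508F	missense	D/D/D	het				0	0	1	S	4
32	M	NCF1	269G>A	R90H	missense	B/D/D	het				0	0	0		3
32	M	NLRP3	292C>G	R98G	missense	B/T/N	het				0	0	0		3
32	M	TGFBR2	449delA	E150fs	frameshift	-/-/-	het				0	0	0		3
33	F	C6	2087A>G	D696G	missense	B/T/D	het				0	0	0		3
33	F	CECR1	1208T>C	M403T	missense	B/T/N	het				0	0	1	M	4
33	F	CECR1	-12233delC	n/a	UTR	-/-/-	het	0.07			0	0	1	S	4
33	F	GLA	C525C>G	D175E	missense	B/T/N	het				0	0	0		3
33	F	NCF1	269G>A	R90H	missense	B/D/D	het				0	0	0		3
33	F	NOTCH3	5296A>G	M1766V	missense	B/T/D	het				0	0	0		3
33	F	RET	2554A>G	I852V	missense	D/T/D	het				0	0	0		3
33	F	TGFBR2	449delA	E150fs	frameshift	-/-/-	het				0	0	0		3
33	F	TTC37	4061A>G	K1354R	missense	P/T/N	het				0	0	0		3
33	F	TTC37	4348G>T	A1450S	missense	D/T/D	het				0	0	0		3
34	M	DOCK8	3079G>A	V1027I	missense	B/T/D	het				0	0	1	S	4
34	M	DOCK8	4041C>A	D1347E	missense	B/T/D	het				0	0	1	S	4
34	M	MASP2	467G>A	C156Y	missense	D/D/D	het				0	0	0		3
34	M	MVK	1156G>A	D386N	missense	B/T/N	het				0	0	0		3
34	M	NCF1	269G>A	R90H	missense	B/D/D	het				0	0	0		3
34	M	NLRP12	2206G>A	G736R	missense	D/T/D	het				0	0	0		3
34	M	PRF1	755A>G	N252S	missense	B/T/A	het				0	0	0		3
35	F	C6	2087A>G	D696G	missense	B/T/D	het				0	0	0		3
35	F	CECR1	937A>G	I313V	missense	B/T/N	het				0	0	1	M	4
35	F	CECR1	-12233delC	n/a	UTR	-/-/-	het	0.07			0	0	1	S	4
35	F	NLRP6	1957C>G	R653G	missense	D/T/N	het				0	0	0		3
35	F	SH3BP2	1686A>G	X562W	missense	-/-/D	het				0	0	0		3
36	F	CFP	521G>T	C174F	missense	D/D/D	het				0	0	0		3
36	F	ELN	2318G>A	G773D	missense	P/-/-	het				0	0	0		3
36	F	HPS4	751TA>	T251S	missense	B/T/N	het				0	0	0		3
36	F	LYN	359A>T	K120I	missense	B/D/D	het				0	0	1	M	4
36	F	NCF1	269G>A	R90H	missense	B/D/D	het				0	0	0		3
36	F	NCF1	299C>T	T100M	missense	P/D/N	het				0	0	0		3
36	F	TRAP1	1330T>A	Y444N	missense	D/D/D	het				0	0	0		3
37	F	ADAM17	2017G>A	V673I	missense	D/T/D	het				0	0	0		3
37	F	BMPR2	2867T>C	I956T	missense	B/-/D	het				0	0	0		3
37	F	LYST	5945C>T	T1982I	missense	B/T/D	het				0	0	0		3
37	F	NCF1	269G>A	R90H	missense	B/D/D	het				0	0	0		3
37	F	TNFRSF1A	362G>A	R92Q	missense	B/T/N	het				0	1	1	S	4
37	F	TRAP1	237G>C	E79D	missense	B/D/D	het				0	0	0		3
38	F	CYBA	179A>C	K60T	missense	B/T/N	het				0	0	0		3
38	F	GUCY2C	2350C>A	Q784K	missense	B/T/N	het				0	0	0		3
38	F	NCF1	269G>A	R90H	missense	B/D/D	het				0	0	0		3
38	F	NLRP12	910C>T	H304Y	missense	D/D/N	het				0	0	0		3
38	F	NLRP3	598G>A	V198M	missense	B/T/N	het				0	1	1	S	4
38	F	NOTCH1	2542G>A	E848K	missense	D/T/D	het				0	0	0		3
38	F	TGFBR1	51_59del:GGCGGCGGC	17_20del	inframe_indel	-/-/-	het				0	0	0		3
38	F	TGFBR2	449delA	E150fs	frameshift	-/-/-	het				0	0	0		3
38	F	VPS13B	8903A>G	N2968S	missense	D/D/A	het				0	0	0		3
39	F	COL7A1	1907G>T	G636V	missense	P/D/D	het				0	0	0		3
39	F	CYBB	1090G>C	G364R	missense	P/T/D	het				0	0	0		3
39	F	FERMT1	1600G>A	A534T	missense	B/T/D	het				0	0	0		3
39	F	GUCY2C	2350C>A	Q784K	missense	B/T/N	het				0	0	0		3
39	F	NCF1	269G>A	R90H	missense	B/D/D	het				0	0	0		3
39	F	NLRP7	1520A>T	E507V	missense	B/T/N	het				0	0	0		3
39	F	SKI	985C>T	P329S	missense	D/T/D	het				0	0	0		3
39	F	TMEM173	761C>T	A254V	missense	B/T/N	het				0	0	0		3
39	F	TRAP1	1330T>A	Y444N	missense	D/D/D	het				0	0	0		3
39	F	TRAP1	947G>A	R316H	missense	P/D/D	het				0	0	0		3
39	F	TRAP1	383G>A	R128H	missense	D/D/D	het				0	0	1	S	4
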