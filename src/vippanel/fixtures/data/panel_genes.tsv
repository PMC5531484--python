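gene	subgroup	inheritance	vip1	vip2
TGFBR1	Aortopathies	AD	1	1
TGFBR2	Aortopathies	AD	1	1
COL5A2	Aortopathies	AD	1	1
BMPR2	Aortopathies	AD	1	1
SKI	Aortopathies	AD	1	1
ELN	Aortopathies	AD	1	1
LYST	Intestinal inflammation	AR	1	1
DOCK8	Intestinal inflammation	AR	1	1
TTC37	Intestinal inflammation	AR	1	1
NCF1	Intestinal inflammation	AR	1	1
NCF2	Intestinal inflammation	AR	1	1
CYBA	Intestinal inflammation	AR	1	1
CYBB	Intestinal inflammation	XL	1	1
IKBKG	Intestinal inflammation	XL	1	1
WAS	Intestinal inflammation	XL	1	1
GUCY2C	Intestinal inflammation	AD	1	1
NLRP6	Intestinal inflammation	AD	1	1
PLCG2	Intestinal inflammation	AD	1	1
MVK	Intestinal inflammation	AR	1	1
HPS4	Intestinal inflammation	AR	1	1
HPS6	Intestinal inflammation	AR	1	1
FERMT1	Intestinal inflammation	AR	1	1
COL7A1	Intestinal inflammation	AR	1	1
ADAM17	Intestinal inflammation	AR	1	1
VPS13B	Intestinal inflammation	AR	1	1
WDR1	Intestinal inflammation	AR	1	1
DCLRE1C	Intestinal inflammation	AR	1	1
TRNT1	Intestinal inflammation	AR	1	1
IFNGR2	Intestinal inflammation	AR	1	1
RET	Intestinal inflammation	AD	1	1
GLA	Intestinal inflammation	XL	1	1
CBS	Intestinal inflammation	AR	1	1
PLOD1	Intestinal inflammation	AR	1	1
AP3B1	Intestinal inflammation	AR	1	1
IL10RA	Intestinal inflammation	AR	1	1
CORO1A	Intestinal inflammation	AR	1	1
FAS	ALPS and related	AD	1	1
FASLG	ALPS and related	AR	1	1
CASP10	ALPS and related	AD	1	1
CASP8	ALPS and related	AR	1	1
SH3BP2	ALPS and related	AD	1	1
PRKCD	ALPS and related	AR	1	1
NLRP3	Autoinflammatory	AD	1	1
TNFRSF1A	Autoinflammatory	AD	1	1
NOD2	Autoinflammatory	AD	1	1
PSTPIP1	Autoinflammatory	AD	1	1
NLRP12	Autoinflammatory	AD	1	1
NLRP7	Autoinflammatory	AD	1	1
LPIN2	Autoinflammatory	AR	1	1
TNFAIP3	Autoinflammatory	AD	1	1
TMEM173	Autoinflammatory	AD	1	1
POMP	Autoinflammatory	AD	1	1
PTEN	Autoinflammatory	AD	1	1
CECR1	Autoinflammatory	AR	1	1
TRAP1	Autoinflammatory	AR	1	1
DNASE2	Autoinflammatory	AR	1	1
LYN	Autoinflammatory	AD	1	1
MEFV	Autoinflammatory	AR	1	1
NLRC4	Autoinflammatory	AD	1	1
IL36RN	Autoinflammatory	AR	1	1
TNFRSF11A	Autoinflammatory	AD	1	1
AP1S3	Autoinflammatory	AD	0	1
C4B	Complement deficiencies	AR	1	1
C5	Complement deficiencies	AR	1	1
C6	Complement deficiencies	AR	1	1
C7	Complement deficiencies	AR	1	1
CFI	Complement deficiencies	AR	1	1
CFP	Complement deficiencies	XL	1	1
CFHR5	Complement deficiencies	AD	1	1
MASP2	Complement deficiencies	AR	1	1
COL3A1	Vascular EDS	AD	1	1
PRF1	HLH	AR	1	1
UNC13D	HLH	AR	1	1
STX11	HLH	AR	1	1
STXBP2	HLH	AR	1	1
SH2D1A	HLH	XL	1	1
XIAP	HLH	XL	0	1
ITK	HLH	AR	0	1
RAB27A	HLH	AR	0	1
TTR	Hereditary amyloidosis	AD	1	1
GSN	Hereditary amyloidosis	AD	1	1
APOA1	Hereditary amyloidosis	AD	1	1
FGA	Hereditary amyloidosis	AD	1	1
LYZ	Hereditary amyloidosis	AD	1	1
B2M	Hereditary amyloidosis	AD	1	1
RNF213	Paediatric stroke	AD	1	1
NOTCH3	Paediatric stroke	AD	1	1
CTC1	Paediatric stroke	AR	1	1
COL4A1	Paediatric stroke	AD	1	1
NOTCH1	Paediatric stroke	AD	1	1
ACTA2	Paediatric stroke	AD	1	1
TREX1	SLE and AGS	AR	1	1
ADAR	SLE and AGS	AR	1	1
RNASEH2A	SLE and AGS	AR	1	1
RNASEH2B	SLE and AGS	AR	1	1
RNASEH2C	SLE and AGS	AR	1	1
SAMHD1	SLE and AGS	AR	1	1
IFIH1	SLE and AGS	AD	1	1
DNASE1	SLE and AGS	AD	1	1
DNASE1L3	SLE and AGS	AR	1	1
C1QA	SLE and AGS	AR	1	1
OTULIN	Vasculitis/vasculopathy	AR	1	1
ISG15	Vasculitis/vasculopathy	AR	1	1
USP18	Vasculitis/vasculopathy	AR	1	1
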