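ABL1
ABL2
ACVR1
ACVR1B
AKT1
AKT2
AKT3
ALK
ALOX12B
AMER1
APC
AR
ARAF
ARFRP1
ARID1A
ARID1B
ARID2
ARID5B
ASXL1
ASXL2
ATM
ATR
ATRX
AURKA
AURKB
AXIN1
AXIN2
AXL
B2M
BAP1
BARD1
BCL2
BCL2L1
BCL2L2
BCL6
BCOR
BCORL1
BCR
BIRC3
BLM
BMPR1A
BRAF
BRCA1
BRCA2
BRD4
BRIP1
BTG1
BTK
CALR
CARD11
CASP8
CBFB
CBL
CCND1
CCND2
CCND3
CCNE1
CD274
CD276
CD79A
CD79B
CDC73
CDH1
CDK12
CDK4
CDK6
CDK8
CDKN1A
CDKN1B
CDKN2A
CDKN2B
CDKN2C
CEBPA
CENPA
CHD2
CHD4
CHEK1
CHEK2
CIC
CREBBP
CRKL
CRLF2
CSF1R
CSF3R
CTCF
CTLA4
CTNNA1
CTNNB1
CUL3
CUL4A
CXCR4
CYLD
CYP17A1
DAXX
DCUN1D1
DDR1
DDR2
DICER1
DIS3
DNAJB1
DNMT1
DNMT3A
DNMT3B
DOT1L
E2F3
EED
EGFL7
EGFR
EIF1AX
EIF4A2
EIF4E
EML4
EP300
EPCAM
EPHA3
EPHA5
EPHA7
EPHB1
ERBB2
ERBB3
ERBB4
ERCC1
ERCC2
ERCC3
ERCC4
ERCC5
ERG
ERRFI1
ESR1
ETS1
ETV1
ETV4
ETV5
ETV6
EWSR1
EZH1
EZH2
FAM46C
FANCA
FANCC
FANCD2
FANCE
FANCF
FANCG
FANCL
FAS
FAT1
FBXW7
FGF10
FGF12
FGF14
FGF19
FGF23
FGF3
FGF4
FGF6
FGFR1
FGFR2
FGFR3
FGFR4
FH
FLCN
FLI1
FLT1
FLT3
FLT4
FOXA1
FOXL2
FOXO1
FOXP1
FRS2
FUBP1
FYN
GABRA6
GATA1
GATA2
GATA3
GATA4
GATA6
GEN1
GID4
GLI1
GNA11
GNA13
GNAQ
GNAS
GPR124
GPS2
GREM1
GRIN2A
GRM3
GSK3B
H3F3A
H3F3B
HGF
HIST1H1C
HIST1H2BD
HIST1H3B
HNF1A
HOXB13
HRAS
HSD3B1
HSP90AA1
ICOSLG
ID3
IDH1
IDH2
IFNGR1
IGF1
IGF1R
IGF2
IKBKE
IKZF1
IL10
IL7R
INHA
INHBA
INPP4A
INPP4B
INSR
IRF2
IRF4
IRS1
IRS2
JAK1
JAK2
JAK3
JUN
KAT6A
KDM5A
KDM5C
KDM6A
KDR
KEAP1
KEL
KIF5B
KIT
KLF4
KLHL6
KMT2A
KMT2B
KMT2C
KMT2D
KRAS
LATS1
LATS2
LMO1
LRP1B
LYN
LZTR1
MAGI2
MALT1
MAP2K1
MAP2K2
MAP2K4
MAP3K1
MAP3K13
MAP3K14
MAPK1
MAPK3
MAX
MCL1
MDC1
MDM2
MDM4
MED12
MEF2B
MEN1
MERTK
MET
MGA
MITF
MLH1
MLH3
MPL
MRE11A
MSH2
MSH3
MSH6
MST1
MST1R
MTOR
MUTYH
MYC
MYCL
MYCN
MYD88
MYOD1
NAB2
NBN
NCOA3
NCOR1
NEGR1
NF1
NF2
NFE2L2
NFKBIA
NKX2-1
NKX3-1
NOTCH1
NOTCH2
NOTCH3
NOTCH4
NPM1
NRAS
NRG1
NSD1
NTRK1
NTRK2
NTRK3
NUP93
NUTM1
PAK1
PAK3
PALB2
PARK2
PARP1
PAX3
PAX5
PAX8
PBRM1
PDCD1
PDCD1LG2
PDGFRA
PDGFRB
PDK1
PGR
PHF6
PHOX2B
PIK3C2B
PIK3C2G
PIK3C3
PIK3CA
PIK3CB
PIK3CD
PIK3CG
PIK3R1
PIK3R2
PIK3R3
PIM1
PLCG2
PLK2
PMAIP1
PMS1
PMS2
PNRC1
POLD1
POLE
PPARG
PPM1D
PPP2R1A
PPP2R2A
PPP6C
PRDM1
PREX2
PRKAR1A
PRKCI
PRKDC
PTCH1
PTEN
PTPN11
PTPRD
PTPRS
PTPRT
QKI
RAC1
RAD21
RAD50
RAD51
RAD51B
RAD51C
RAD51D
RAD52
RAD54L
RAF1
RANBP2
RARA
RASA1
RB1
RBM10
RECQL4
REL
RET
RFWD2
RHEB
RHOA
RICTOR
RIT1
RNF43
ROS1
RPS6KA4
RPS6KB1
RPS6KB2
RPTOR
RUNX1
RUNX1T1
RYBP
SDHA
SDHAF2
SDHB
SDHC
SDHD
SETBP1
SETD2
SF3B1
SGK1
SH2B3
SH2D1A
SHQ1
SLIT2
SLX4
SMAD2
SMAD3
SMAD4
SMARCA4
SMARCB1
SMARCD1
SMC1A
SMC3
SMO
SNCAIP
SOCS1
SOX10
SOX17
SOX2
SOX9
SPEN
SPOP
SPTA1
SRC
SRSF2
STAG2
STAT3
STAT4
STAT5A
STAT5B
STK11
STK40
SUFU
SUZ12
SYK
TAF1
TBX3
TCEB1
TCF3
TCF7L2
TERT
TET1
TET2
TET3
TGFBR1
TGFBR2
TMEM127
TMPRSS2
TNFAIP3
TNFRSF14
TOP1
TOP2A
TP53
TP63
TRAF2
TRAF7
TSC1
TSC2
TSHR
U2AF1
VEGFA
VHL
WISP3
WT1
XPO1
XRCC2
YAP1
YES1
ZBTB2
ZFHX3
ZNF217
ZNF703
ZRSR2
BCL10
BCL11A
BCL11B
CD28
CD36
CDX2
CIITA
CUX1
DDX3X
DROSHA
EPHB4
ERF
FANCI
FANCM
FEV
GPC3
HDAC1
HDAC2
IRS4
KDM2B
KLF5
MAF
MAFB
NCOA2
NCOR2
NFKB1
NFKB2
PDGFB
PIK3R4
POLQ
PRDM16
PTPN1
PTPN2
RASA2
RRAGC
SESN1
SESN2
SESN3
SHOC2
SLFN11
SMYD3
SOS1
SPRED1
STAG1
TAP1
TAP2
TBL1XR1
TENT5C
TLR4
TRAF3
TRAF5
UBA1
UBR5
USP8
VAV1
WHSC1
WRN
XIAP
ZMYM3
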