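# Default 105-gene cancer panel (synthetic stand-in).
# The 13 HR and 6 MMR genes are the published sets; the remainder is a
# representative cancer-gene list, editable / replaceable by the user.
AKT1
APC
AR
ARID1A
ATM
ATR
AURKA
BAP1
BARD1
BCL2
BRAF
BRCA1
BRCA2
BRIP1
CCND1
CCNE1
CDH1
CDK4
CDK6
CDKN1B
CDKN2A
CHEK1
CHEK2
CTNNB1
DDR2
EGF
EGFR
ERBB2
ERBB3
ERBB4
ESR1
EZH2
FANCA
FANCC
FANCD2
FBXW7
FGFR1
FGFR2
FGFR3
FGFR4
FLT3
GATA3
HRAS
HSPH1
IDH1
IDH2
IGF1R
JAK2
KDR
KIT
KRAS
MAP2K1
MAP3K1
MCL1
MDM2
MDM4
MET
MLH1
MLH3
MSH2
MSH3
MSH6
MTOR
MUS81
MYC
MYCN
NBN
NF1
NF2
NOTCH1
NOTCH2
NRAS
NTRK1
PALB2
PDGFRA
PDGFRB
PIK3CA
PIK3R1
PMS2
POLD1
PTCH1
PTEN
RAD50
RAD51
RAD51B
RAD51C
RAD51D
RAF1
RB1
RET
ROS1
RUNX1
SMAD4
SMARCA4
SMO
SRC
STK11
TERT
TOP2A
TP53
TSC1
TSC2
VHL
XRCC2
XRCC3
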