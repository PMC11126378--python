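# Illustrative 62-gene skeletal-dysplasia panel.  The gene of interest is
# HSPG2; the remaining 61 symbols are well-known skeletal-dysplasia genes
# included to give the panel a realistic size and composition.  This is NOT
# a transcription of any published panel.
HSPG2
ACAN
ALPL
ARSB
B3GALT6
B3GAT3
B4GALT7
BMP1
CANT1
CHST3
CHST14
COL1A1
COL1A2
COL2A1
COL9A1
COL9A2
COL9A3
COL10A1
COL11A1
COL11A2
COMP
CREBBP
CRTAP
DDR2
DYM
DYNC2H1
EBP
EVC
EVC2
FBN1
FGFR1
FGFR2
FGFR3
FLNA
FLNB
GDF5
GPX4
IHH
IFT80
IMPAD1
LBR
MATN3
MMP13
NEK1
NPR2
P3H1
PCNT
PEX7
PTH1R
ROR2
RUNX2
SEDL
SLC26A2
SLC35D1
SMARCAL1
SOX9
TRAPPC2
TRIP11
TRPV4
WDR19
WDR35
WISP3
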