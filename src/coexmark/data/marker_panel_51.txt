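# 51-transcript blood marker panel (gene symbols)
AKAP8L
APLP2
ARAF
ARHGEF40
ATP6V1H
BNIP3L
BRAF
C21orf7
CD59
COMMD9
CTGF
ENPP4
FAM131A
FZD7
GLT8D1
HDAC9
HSF2
KRAS
LEO1
MKI67
MORF4L2
NAP1L1
NOL3
NUDT3
OAZ2
PANK2
PHF21A
PKD1
PLD3
PNMA2
PQBP1
RAF1
RNF41
RSF1
RTN2
SLC18A1
SLC18A2
SMARCD3
SPATA7
SSTR1
SSTR3
SSTR4
SSTR5
TECPR2
TPH1
TRMT112
VPS13C
WDFY3
ZFHX3
ZXDC
ZZZ3
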