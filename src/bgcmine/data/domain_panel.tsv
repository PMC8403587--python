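domain	length
A	320
ACP	70
AT	240
C	300
CDPS	200
CMeT	130
CS	320
DH	150
DMAT	300
E	260
ER	220
FAS_alpha	320
FAS_beta	320
GGPPS	240
GT	280
KR	200
KS	300
LSS	340
PT	200
PTase	240
R	250
SAT	180
SHC	340
T	70
TC	260
TE	180
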