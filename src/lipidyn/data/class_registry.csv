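class_code,category,n_chains,aliases
PC,pl,2,
PE,pl,2,
PS,pl,2,
PI,pl,2,
PA,pl,2,
PG,pl,2,
CL,pl,4,
LBPA,pl,2,BMP
LPC,pl,1,
LPE,pl,1,
LPG,pl,1,
LPS,pl,1,
LPI,pl,1,
LPA,pl,1,
SM,spl,2,
Cer,spl,2,
GluCer,spl,2,
LacCer,spl,2,
GM3,spl,2,
Gb3,spl,2,
SL,spl,2,
S1P,spl,1,
Sph,spl,1,
TAG,neutral,3,
DAG,neutral,2,
FFA,neutral,1,
Cho,neutral,0,
CE,neutral,1,
CAR,neutral,1,acylcarnitine
CoA,neutral,1,acyl-CoA
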