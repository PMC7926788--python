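# synthetic stand-in: FA-like ligand codes excluded from negative pools
PLM
MYR
OLA
STE
DAO
LAU
OCA
ACD
EPA
DHA
LNL
HXA
ELA
VCA
PAM
DKA
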