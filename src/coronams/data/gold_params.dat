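# Amino-acid-gold Lennard-Jones parameters (per gold atom; the engine
# scales epsilon by the surface-contact factor, default 13).
# PLACEHOLDER values -- replace with a calibrated amino-acid-gold set for
# quantitative contact statistics.
# residue  epsilon(kcal/mol)  sigma(A)
ALA  0.1000  5.0000
CYS  0.1400  5.0000
ASP  0.1800  5.0000
GLU  0.1800  5.0000
PHE  0.1000  5.0000
GLY  0.1000  5.0000
HIS  0.1800  5.0000
ILE  0.1000  5.0000
LYS  0.1800  5.0000
LEU  0.1000  5.0000
MET  0.1000  5.0000
ASN  0.1400  5.0000
PRO  0.1000  5.0000
GLN  0.1400  5.0000
ARG  0.1800  5.0000
SER  0.1400  5.0000
THR  0.1400  5.0000
VAL  0.1000  5.0000
TRP  0.1400  5.0000
TYR  0.1400  5.0000
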