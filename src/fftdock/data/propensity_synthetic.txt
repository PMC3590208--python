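# Natural-log interface propensity l_p per residue type.
# SYNTHETIC stand-in table: only the extremes of the published propensity
# scale are public (-0.38 for ASP, 0.83 for TRP); the remaining 18 residues
# are filled by a linear interpolation over a hydrophobicity/aromaticity
# ranking (aromatic & hydrophobic residues interface-prone, charged residues
# interface-averse).  Format: RES3 value
TRP  0.830
PHE  0.766
MET  0.703
TYR  0.639
ILE  0.575
LEU  0.512
CYS  0.448
VAL  0.384
HIS  0.321
ARG  0.257
ALA  0.193
GLY  0.130
THR  0.066
SER  0.002
ASN -0.062
GLN -0.125
PRO -0.189
GLU -0.253
LYS -0.316
ASP -0.380
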