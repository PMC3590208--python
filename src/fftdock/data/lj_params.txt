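# Lennard-Jones well depths and homogeneous-pair contact distances per
# element class, Amber-style values (epsilon kcal/mol, r* Angstrom).
# Format: ELEMENT epsilon rstar
H 0.0157 0.600
C 0.0860 1.908
N 0.1700 1.824
O 0.2100 1.661
S 0.2500 2.000
P 0.2000 2.100
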