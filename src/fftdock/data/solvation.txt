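# Per-element atomic solvation parameters sigma_i (kcal/mol/A^2) for the
# SASA-weighted solute-solvent dispersion term, plus global constants:
# solvent pressure p (kcal/mol/A^3) and cavity surface tension gamma
# (kcal/mol/A^2).  Documented package defaults; all overridable in config.
pressure 0.008
gamma 0.0072
H  0.000
C  0.012
N -0.022
O -0.038
S  0.012
P -0.010
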