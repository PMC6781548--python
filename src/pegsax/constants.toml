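# Physical constants and species data used throughout the package.
# Molar masses are computed from molecular formulas with IUPAC 2021
# atomic weights (H 1.008, C 12.011, N 14.007, O 15.999), in g/mol.

[physical]
gas_constant = 8.314462618   # J mol^-1 K^-1
kcal_to_kj = 4.184           # thermochemical calorie
water_ionization_kw = 1.0e-14  # mol^2 L^-2, default at all temperatures

[molar_mass]
# PEG is tracked in monomer (oxyethylene) equivalents, C2H4O.
PEG = 44.053
GA = 76.051    # glycolic acid, C2H4O3
A = 44.053     # acetaldehyde, C2H4O
F = 30.026     # formaldehyde, CH2O
FA = 46.025    # formic acid, CH2O2
SAXA = 315.417 # saxagliptin free base, C18H25N3O2
SCA = 297.402  # saxagliptin cyclic amidine, C18H23N3O (SAXA - H2O)
ESCA = 297.402 # epimer of SCA, same formula
SFA = 343.427  # saxagliptin formyl amide, C19H25N3O3 (SAXA + FA - H2O)

[ph_closure]
# Linear micro-environmental pH model: pH = intercept + slope * w_FA,
# with w_FA the formic-acid mass fraction of the film coat (kg/kg).
slope = -570.45
intercept = 5.6703
floor = 1.0

[phase_lookup]
# Fraction of PEG out of phase (melt-mobile, hence reactive) as a function
# of the PEG weight fraction relative to total film polymer, from published
# DSC melt-behaviour measurements of PEG/high-melting-polymer films.
ratios = [0.10, 0.20, 0.30]
fractions = [0.00, 0.05, 0.22]
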