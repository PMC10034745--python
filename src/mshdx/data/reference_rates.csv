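# Poly-DL-alanine reference rate constants and temperature parameters for
# backbone amide H->D exchange in D2O, after Bai et al. (1993) Proteins
# 17:75-86. Rates are log10 of min^-1 (water) or M^-1 min^-1 (acid/base)
# at the 293 K reference temperature; activation energies in kcal/mol.
# pKD is the D2O autoionization pK at 293 K; dH_ion its van't Hoff enthalpy.
# Side-chain pK values are D2O (glass-electrode-corrected) constants used to
# blend protonation states of Asp, Glu, His and the C-terminal carboxyl.
# Table version: bai1993-d2o-v1
name,value
log10_ka_ref,1.62
log10_kb_ref,10.05
log10_kw_ref,-1.50
Ea_acid_kcal,14.0
Ea_base_kcal,17.0
Ea_water_kcal,19.0
T_ref_K,293.0
pKD_ref,15.05
dH_ion_kcal,14.17
pK_asp,4.48
pK_glu,4.93
pK_his,7.42
pK_cterm,4.00
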