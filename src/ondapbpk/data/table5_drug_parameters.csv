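parameter,value,unit
molecular_weight,293.4,g/mol
log_p,2.25,log units
binding_protein,albumin,
solubility,0.36,mg/L
pka_base,7.40,pH units
specific_intestinal_permeability,2.24e-5,cm/min
specific_organ_permeability,8.02e-3,cm/min
fu_plasma,0.27,fraction
clint_cyp1a2,0.21,L/min
clint_cyp3a4,0.03,L/min
renal_clearance_specific,0.13,mL/min/kg
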