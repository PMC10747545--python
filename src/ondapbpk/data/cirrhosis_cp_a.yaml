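# Child-Pugh A (mild) cirrhosis physiology scalers.
# Entries are fractions/multipliers of the healthy control value except
# hematocrit_value, which is the absolute hematocrit of the diseased
# population. CYP1A2 entries are whole-liver activity fractions; CYP3A4
# entries are abundances per unit functional liver mass and are combined
# with functional_liver_mass downstream.
cp_class: A
functional_liver_mass: 0.69
cyp3a4_fraction: 0.589
cyp1a2_fraction: 0.63
albumin_fraction: 0.84
hematocrit_value: 0.39
portal_flow_fraction: 0.4
hepatic_arterial_flow_factor: 1.3
other_organs_flow_factor: 1.75
renal_flow_fraction: 0.88
gfr_fraction: 0.7
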