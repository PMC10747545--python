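parameter,control,cp_a,cp_b,cp_c
functional_liver_mass,2.38,0.69,0.55,0.28
cyp3a4_fraction,4.32,0.589,0.4,0.4
cyp1a2_fraction,1.8,0.63,0.26,0.12
albumin_fraction,1,0.84,0.69,0.53
hematocrit_value,0.47,0.39,0.37,0.35
portal_flow_fraction,1.21,0.4,0.36,0.04
hepatic_arterial_flow_factor,17.94,1.3,2.3,3.4
other_organs_flow_factor,,1.75,2.25,2.75
renal_flow_fraction,302.71,0.88,0.65,0.48
gfr_fraction,116,0.7,0.58,0.55
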