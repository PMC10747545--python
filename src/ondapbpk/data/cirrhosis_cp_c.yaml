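# Child-Pugh C (severe) cirrhosis physiology scalers. See cirrhosis_cp_a.yaml
# for field semantics.
cp_class: C
functional_liver_mass: 0.28
cyp3a4_fraction: 0.4
cyp1a2_fraction: 0.12
albumin_fraction: 0.53
hematocrit_value: 0.35
portal_flow_fraction: 0.04
hepatic_arterial_flow_factor: 3.4
other_organs_flow_factor: 2.75
renal_flow_fraction: 0.48
gfr_fraction: 0.55
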