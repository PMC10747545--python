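# Child-Pugh B (moderate) cirrhosis physiology scalers. See cirrhosis_cp_a.yaml
# for field semantics.
cp_class: B
functional_liver_mass: 0.55
cyp3a4_fraction: 0.4
cyp1a2_fraction: 0.26
albumin_fraction: 0.69
hematocrit_value: 0.37
portal_flow_fraction: 0.36
hepatic_arterial_flow_factor: 2.3
other_organs_flow_factor: 2.25
renal_flow_fraction: 0.65
gfr_fraction: 0.58
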