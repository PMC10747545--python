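# Ondansetron drug parameter set.
#
# Physicochemical/ADME inputs mirror the published compound record
# (moderately lipophilic weak base, albumin-bound, CYP1A2/CYP3A4
# metabolized, minor renal elimination). The calibration block holds the
# frozen outputs of the one-time model calibration (see
# ondapbpk.calibration): a single multiplicative factor on total hepatic
# intrinsic clearance fitted to the healthy reference IV exposure, and the
# first-order absorption constant fitted to the healthy oral peak.
name: ondansetron
molecular_weight: 293.4        # g/mol
log_p: 2.25                    # octanol:water, log units
pka_base: 7.40
fu_plasma: 0.27                # fraction unbound in plasma
solubility: 0.36               # mg/L
binding_protein: albumin
specific_intestinal_permeability: 2.24e-5   # cm/min
specific_organ_permeability: 8.02e-3        # cm/min (recorded; organs are perfusion-limited)
clint_cyp1a2: 0.21             # L/min, relative pathway weight
clint_cyp3a4: 0.03             # L/min, relative pathway weight
renal_clearance_specific: 0.13 # mL/min/kg
calibration:
  calibration_factor: 9.500920   # multiplies (clint_cyp1a2 + clint_cyp3a4)
  ka_per_h: 0.992468             # first-order absorption rate constant
  fa: 1.0                      # fraction entering the absorption depot
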