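# Reference adult human anatomy/physiology for the whole-body model.
#
# Volumes (L) and resting regional blood flows (L/min blood) follow
# ICRP-style reference-man tabulations for a 73 kg adult; tissue
# composition fractions (volume fraction of water, neutral lipid and
# phospholipid) are the published values used with the Poulin-Theil
# tissue:plasma partitioning model. The liver row carries total hepatic
# inflow (hepatic artery + portal vein); portal flow is the sum of the
# gut and spleen rows. Lung flow equals cardiac output (pass-through).
body_weight_kg: 73.0
hematocrit: 0.47
gfr_ml_min: 116.0
plasma_composition:
  water_fraction: 0.96
  neutral_lipid_fraction: 0.0035
  phospholipid_fraction: 0.00225
erythrocyte_water_fraction: 0.63
organs:
  lung:           {volume: 0.50,  blood_flow: 6.500, water_fraction: 0.811, neutral_lipid_fraction: 0.0030, phospholipid_fraction: 0.0090}
  heart:          {volume: 0.33,  blood_flow: 0.260, water_fraction: 0.758, neutral_lipid_fraction: 0.0115, phospholipid_fraction: 0.0166}
  brain:          {volume: 1.45,  blood_flow: 0.780, water_fraction: 0.770, neutral_lipid_fraction: 0.0510, phospholipid_fraction: 0.0565}
  muscle:         {volume: 29.00, blood_flow: 1.105, water_fraction: 0.760, neutral_lipid_fraction: 0.0220, phospholipid_fraction: 0.0072}
  adipose:        {volume: 13.00, blood_flow: 0.325, water_fraction: 0.180, neutral_lipid_fraction: 0.7900, phospholipid_fraction: 0.0020}
  skin:           {volume: 3.40,  blood_flow: 0.325, water_fraction: 0.718, neutral_lipid_fraction: 0.0284, phospholipid_fraction: 0.0111}
  bone:           {volume: 10.20, blood_flow: 0.325, water_fraction: 0.439, neutral_lipid_fraction: 0.0740, phospholipid_fraction: 0.0011}
  liver:          {volume: 1.80,  blood_flow: 1.550, water_fraction: 0.751, neutral_lipid_fraction: 0.0348, phospholipid_fraction: 0.0252}
  gut:            {volume: 1.20,  blood_flow: 0.930, water_fraction: 0.718, neutral_lipid_fraction: 0.0487, phospholipid_fraction: 0.0163}
  spleen:         {volume: 0.19,  blood_flow: 0.200, water_fraction: 0.788, neutral_lipid_fraction: 0.0201, phospholipid_fraction: 0.0198}
  kidney:         {volume: 0.31,  blood_flow: 1.235, water_fraction: 0.783, neutral_lipid_fraction: 0.0207, phospholipid_fraction: 0.0162}
  rest-of-body:   {volume: 3.30,  blood_flow: 0.595, water_fraction: 0.740, neutral_lipid_fraction: 0.0400, phospholipid_fraction: 0.0200}
  arterial blood: {volume: 1.50,  blood_flow: 6.500, water_fraction: 0.810, neutral_lipid_fraction: 0.0020, phospholipid_fraction: 0.0020}
  venous blood:   {volume: 3.30,  blood_flow: 6.500, water_fraction: 0.810, neutral_lipid_fraction: 0.0020, phospholipid_fraction: 0.0020}
hepatic_arterial_flow: 0.42
portal_flow: 1.13
renal_flow: 1.235
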