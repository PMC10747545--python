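study_id,route,dose_mg,dose_mg_per_kg,infusion_min,n,female_n,age_low,age_high,age_mean,age_sd,weight_low,weight_high,weight_mean,weight_sd,population
b20,iv,8,,15,32,0,18,40,,,58.3,95.8,,,healthy
b22,iv,8,,5,6,2,19,23,,,,,,,healthy
b23,iv,8,,5,6,2,32,43,,,50,80,,,healthy
b21,iv,8,,15,6,0,19,35,,,55.5,90.5,,,healthy
b24,iv,,0.15,15,11,5,,,31,7,,,66.1,8.5,healthy
b27,oral,24,,,12,6,,,,,,,,,healthy
b26,oral,8,,,22,11,18,41,,,49,94,,,healthy
b25,oral,8,,,24,0,19,39,,,60,90,,,healthy
b24,oral,8,,,11,5,,,31,7,,,66.1,8.5,healthy
b20,oral,8,,,32,0,18,40,,,58.3,95.8,,,healthy
b30,iv,8,,5,19,8,20,69,,,,,,,disease
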