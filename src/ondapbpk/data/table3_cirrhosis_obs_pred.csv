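study_id,route,parameter,observed,predicted,printed_ratio
cp_a,iv,auc_0inf,633,476.46,1.33
cp_a,iv,cmax,113.7,323.39,0.35
cp_a,iv,cl,2.89,3.81,0.76
cp_b,iv,auc_0inf,641,801.90,0.80
cp_b,iv,cmax,174.6,274.22,0.64
cp_b,iv,cl,2.84,2.28,1.25
cp_c,iv,auc_0inf,1383,1208.94,1.14
cp_c,iv,cmax,149.5,251.84,0.60
cp_c,iv,cl,1.32,1.51,0.87
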