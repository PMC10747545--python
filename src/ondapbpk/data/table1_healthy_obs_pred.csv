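study_id,route,parameter,observed,predicted,printed_ratio
b20,iv,auc_0inf,246.5,271.06,0.91
b20,iv,cmax,102.5,170.69,0.60
b20,iv,cl,7.41,6.73,1.10
b22,iv,auc_0inf,279,324.87,0.86
b22,iv,cmax,161,344.15,0.47
b22,iv,cl,6.54,5.70,1.15
b23,iv,auc_0inf,257,315.18,0.82
b23,iv,cmax,343,315.95,1.09
b23,iv,cl,7.10,5.70,1.25
b21,iv,auc_0inf,313,278.54,1.12
b21,iv,cmax,159,166.97,0.95
b21,iv,cl,6.7,6.52,1.03
b24,iv,auc_0inf,435.46,372.41,1.17
b24,iv,cmax,170,225.86,0.75
b24,iv,cl,5.81,6.76,0.86
b27,oral,auc_0inf,805.9,777.09,1.04
b27,oral,cmax,94.6,82.81,1.14
b27,oral,cl,8.64,7.02,1.23
b26,oral,auc_0inf,244.496,280.70,0.87
b26,oral,cmax,36.113,30.69,1.18
b26,oral,cl,8.06,6.52,1.24
b25,oral,auc_0inf,246.1,247.22,1.00
b25,oral,cmax,26.3,26.68,0.99
b25,oral,cl,7.42,7.31,1.01
b24,oral,auc_0inf,209.27,266.78,0.78
b24,oral,cmax,32.57,29.34,1.11
b24,oral,cl,8.9,7.47,1.19
b20,oral,auc_0inf,168.8,246.96,0.68
b20,oral,cmax,26.4,27.73,0.95
b20,oral,cl,10.8,7.28,1.48
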