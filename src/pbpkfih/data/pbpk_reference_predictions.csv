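dose_mg,cmax_pred,cmax_obs,cmax_fe,auc_0inf_pred,auc_0inf_obs,auc_0inf_fe
2,0.41,0.66,0.62,7.62,13.37,0.57
6,1.23,1.28,0.96,22.86,25.33,0.90
12,2.45,2.90,0.84,45.72,45.30,1.01
24,4.85,5.84,0.80,91.42,112.84,0.81
40,8.15,12.30,0.66,152.45,270.40,0.56
60,12.26,12.30,1.00,228.63,278.36,0.82
90,18.54,17.90,1.04,343.01,398.77,0.86
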