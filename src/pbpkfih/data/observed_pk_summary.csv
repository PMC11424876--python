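dose_mg,n,tmax_median,tmax_min,tmax_max,cmax_geomean,cmax_geocv_pct,auc_0t_geomean,auc_0t_geocv_pct,auc_0inf_geomean,auc_0inf_geocv_pct,t_half_geomean,t_half_geocv_pct,cl_f_geomean,cl_f_geocv_pct
2,2,3.50,2.00,5.00,0.732,86.2,10.8,61.2,11.9,59.1,13.7,2.7,168,59.1
6,8,4.00,3.00,6.00,1.43,36.7,23.0,26.5,24.7,24.7,15.7,15.5,243,24.7
12,8,4.00,3.00,6.00,2.50,76.5,37.7,66.5,39.4,62.9,14.6,17.0,304,62.9
24,8,3.00,2.00,5.00,6.51,31.4,105,28.5,107,27.8,15.5,15.7,224,27.8
40,8,4.50,1.50,6.00,11.4,82.6,215,68.7,220,68.6,18.2,9.8,182,68.6
60,8,3.50,1.50,6.12,13.5,47.1,253,45.4,257,45.1,16.4,6.9,234,45.1
90,8,3.00,1.00,8.00,20.5,18.1,364,35.1,369,35.5,14.9,13.7,234,35.5
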