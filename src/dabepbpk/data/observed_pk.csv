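set_id,role,dose_mg,formulation,metric,observed,simulated,cv_percent,n_inferred,criteria_lo,criteria_hi,bound_type
1,training,0.375,solution_with_precipitation,cmax,0.17,0.15,,,0.09,0.34,twofold
1,training,0.375,solution_with_precipitation,auc,1.44,1.44,,,0.72,2.88,twofold
2,training,300,solid_IR,cmax,174,166,,,87,348,twofold
2,training,300,solid_IR,auc,1220,1181,,,610,2440,twofold
3,training,200,solution_with_precipitation,cmax,145,151,31.03,10,96,218,cv
3,training,200,solution_with_precipitation,auc,930,1166,24.95,10,668,1295,cv
4sd,qualification,400,solution_with_precipitation,cmax,281,249,,,140,562,twofold
4sd,qualification,400,solution_with_precipitation,auc,1254,1128,,,627,2508,twofold
4md,qualification,400,solution_with_precipitation,cmax,662,334,,,331,1324,twofold
4md,qualification,400,solution_with_precipitation,auc,5071,2805,,,2535,10142,twofold
5,qualification,150,solid_IR,cmax,107,124,67.29,10,47,244,cv
5,qualification,150,solid_IR,auc,937,965,69.26,10,403,2178,cv
6,qualification,0.75,solution_with_precipitation,cmax,0.38,0.33,,,0.19,0.76,twofold
6,qualification,0.75,solution_with_precipitation,auc,3.11,3.10,,,1.56,6.22,twofold
9,qualification,300,solid_IR,cmax,83,170,66,60,60,116,cv
9,qualification,300,solid_IR,auc,547,1239,77,60,376,796,cv
10_11,qualification,150,solid_IR,cmax,63,105,122,20,25,156,cv
10_11,qualification,150,solid_IR,auc,536,793,110,20,229,1252,cv
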