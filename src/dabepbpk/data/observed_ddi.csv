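set_id,role,dose_mg,perpetrator,metric,observed,simulated,guest_lo,guest_hi
1,training,0.375,ctc,cmax_ratio,4.57,4.46,2.57,8.14
1,training,0.375,ctc,auc_ratio,4.02,4.64,2.30,7.04
2,training,300,ctc,cmax_ratio,1.60,1.61,1.16,2.20
2,training,300,ctc,auc_ratio,1.49,1.97,1.12,1.98
6,qualification,0.75,rf,cmax_ratio,1.86,2.16,1.27,2.72
6,qualification,0.75,rf,auc_ratio,2.22,1.94,1.49,3.68
7,qualification,0.375,itz,cmax_ratio,6.42,4.82,3.48,11.84
7,qualification,0.375,itz,auc_ratio,6.92,5.12,3.73,12.84
8,qualification,0.375,rf,cmax_ratio,1.78,2.16,1.24,2.56
8,qualification,0.375,rf,auc_ratio,2.32,1.94,1.51,3.76
9,qualification,300,ctc,cmax_ratio,1.71,1.61,1.21,2.42
9,qualification,300,ctc,auc_ratio,1.97,1.97,1.32,2.94
10,qualification,150,vp,cmax_ratio,2.15,1.55,1.40,3.30
10,qualification,150,vp,auc_ratio,1.98,1.88,1.32,2.96
11,qualification,150,vp_1h,cmax_ratio,2.70,1.74,1.66,4.40
11,qualification,150,vp_1h,auc_ratio,2.37,2.07,1.50,3.74
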