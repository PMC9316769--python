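analyte,slope,intercept,r2,range_low_ug_ml,range_high_ug_ml,loq_ug_ml,lod_ug_ml,stability_rsd_pct,precision_rsd_pct,repeatability_rsd_pct,recovery_mean_pct,recovery_rsd_pct
cynaroside,13.984,-3.0103,0.9997,2.86,143.0,0.0091,0.0046,0.85,0.75,2.1,98.52,0.62
narirutin,14.502,-4.3899,0.9996,21.74,1088.0,0.015,0.0076,0.2,0.72,1.54,99.09,1.1
apigenin-7-O-glucuronide,12.039,-44.602,0.9995,3.98,199.0,0.082,0.027,1.24,0.74,1.97,101.74,0.87
rosmarinic acid,17.283,-34.682,0.9996,3.7,195.0,0.017,0.0065,0.66,0.78,1.82,102.62,0.87
buddleoside,2.4643,-1.4829,0.9995,2.6,160.0,0.045,0.018,0.45,0.7,1.57,98.51,0.42
luteolin,6.3739,-3.0096,0.9996,1.14,57.0,0.28,0.14,1.97,2.89,2.52,100.04,0.55
isosakuranetin-7-O-rutinoside,8.5706,1.4295,0.9995,21.52,1076.0,0.016,0.0081,0.22,0.76,1.54,101.17,1.81
naringenin,20.834,-0.4984,0.9995,1.4,70.0,0.027,0.013,0.65,0.94,1.08,98.28,1.03
apigenin,11.296,-1.6736,0.9996,1.26,63.0,0.041,0.017,0.57,0.95,2.14,99.72,1.05
buddlejasaponin IVb,14.782,-4.4511,0.9998,1.01,101.0,0.014,0.007,2.48,1.86,2.22,101.31,1.4
isosakuranetin,22.297,-4.2959,0.9996,2.0,100.0,0.024,0.0089,0.21,0.74,1.03,97.3,0.85
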