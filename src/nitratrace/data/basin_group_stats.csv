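region,water_type,n,tn_mean,tn_sd,no3_mean,no3_sd,nh4_mean,nh4_sd,d15N_mean,d15N_sd,d18O_mean,d18O_sd
Lake,surface,6,1.86,0.18,1.63,0.21,0.21,0.05,5.59,1.08,3.28,0.78
ZXHs,surface,11,2.25,0.58,2.08,0.57,0.16,0.06,4.73,1.91,5.67,1.43
ZXHd,ground,3,5.56,2.17,5.41,2.13,0.14,0.04,14.23,4.20,8.11,3.21
DDKs,surface,6,1.91,0.14,1.41,0.36,0.63,0.11,6.31,2.30,1.42,1.47
DDKd,ground,21,7.50,4.78,7.28,4.81,0.17,0.06,14.66,5.26,8.27,3.36
TTHs,surface,6,2.16,0.35,2.01,0.40,0.25,0.21,4.71,2.07,5.77,1.67
TTHd,ground,9,5.30,1.84,5.11,1.88,0.13,0.05,9.71,6.05,7.51,4.10
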