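name,isotope,vx,clogd,f_p,f_nd,bmax_hab,bmax_mab,bmax_lab,ki_high,ki_low,f_p_sd,f_p_n,f_nd_sd,f_nd_n,bmax_hab_sd,bmax_hab_n,bmax_mab_sd,bmax_mab_n,bmax_lab_sd,bmax_lab_n,ki_high_sd,ki_high_n,ki_low_sd,ki_low_n
18F-PBR111,F18,3.10,4.0,0.19,0.06,193,186,99.4,15.6,61.8,0.018,6,0.005,6,66,6,37,4,35,5,3.7,5,10.7,5
11C-PBR28,C11,2.69,2.8,0.16,0.07,193,186,99.4,3.40,188,0.044,6,0.006,6,66,6,37,4,35,5,0.2,6,7.0,5
11C-DPA713,C11,2.91,3.0,0.33,0.12,193,186,99.4,15.0,66.4,0.034,6,0.006,6,66,6,37,4,35,5,2.2,5,7.8,4
11C-(R)-PK11195,C11,2.74,4.9,0.14,0.01,433,433,506,28.3,22.3,0.039,4,0.002,6,154,9,154,9,131,5,4.0,6,2.2,5
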