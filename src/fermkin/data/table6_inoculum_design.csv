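x1,x2,x3,pH_mean,pH_sd,pH_n,tta_pct_mean,tta_pct_sd,tta_pct_n,viscosity_mPas_mean,viscosity_mPas_sd,viscosity_mPas_n
0.050,0.050,0.050,3.58,0.15,3,0.59,0.06,3,6.68,4.42,3
0.050,0.050,0.100,3.57,0.16,3,0.61,0.09,3,1.32,1.76,3
0.050,0.100,0.050,3.63,0.18,3,0.59,0.08,3,6.48,4.01,3
0.050,0.100,0.100,3.63,0.20,3,0.56,0.02,3,5.72,5.96,3
0.075,0.075,0.075,3.57,0.16,3,0.59,0.04,3,6.71,1.71,3
0.100,0.050,0.050,3.61,0.17,3,0.55,0.03,3,2.11,0.84,3
0.100,0.050,0.100,3.76,0.11,3,0.54,0.03,3,5.17,3.98,3
0.100,0.100,0.050,3.52,0.14,3,0.61,0.02,3,4.62,4.84,3
0.100,0.100,0.100,3.64,0.20,3,0.59,0.06,3,10.67,0.81,3
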