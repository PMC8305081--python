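time_h,pH_mean,pH_sd,pH_n,tta_pct_mean,tta_pct_sd,tta_pct_n,glucose_pct_mean,glucose_pct_sd,glucose_pct_n,lab_log10cfu_mean,lab_log10cfu_sd,lab_log10cfu_n,tvc_log10cfu_mean,tvc_log10cfu_sd,tvc_log10cfu_n
0,6.37,0.15,3,0.12,0.01,3,0.55,0.10,3,7.04,0.95,3,6.98,0.05,3
3,6.09,0.13,3,0.14,0.04,3,0.80,0.07,3,6.73,0.46,3,7.38,0.40,3
6,5.59,0.09,3,0.18,0.01,3,1.12,0.10,3,7.74,0.47,3,7.92,0.14,3
9,5.41,0.07,3,0.26,0.03,3,1.57,0.07,3,6.76,0.02,3,7.84,0.34,3
12,4.68,0.09,3,0.31,0.01,3,1.62,0.03,3,7.87,0.34,3,7.89,0.19,3
15,4.36,0.17,3,0.37,0.03,3,1.92,0.05,3,8.10,1.01,3,7.51,0.04,3
18,4.06,0.06,3,0.42,0.01,3,1.89,0.03,3,7.79,0.25,3,7.80,0.26,3
21,3.96,0.03,3,0.45,0.01,3,1.77,0.06,3,8.00,0.56,3,7.72,0.19,3
24,3.90,0.05,3,0.45,0.03,3,2.03,0.03,3,7.99,0.40,3,7.78,0.16,3
27,3.84,0.06,3,0.49,0.02,3,1.91,0.05,3,8.01,0.28,3,7.82,0.08,3
30,3.81,0.04,3,0.48,0.02,3,2.01,0.02,3,7.97,0.43,3,7.29,0.27,3
33,3.78,0.03,3,0.52,0.02,3,2.12,0.09,3,7.92,1.24,3,7.37,0.24,3
36,3.77,0.01,3,0.53,0.03,3,2.05,0.03,3,7.68,0.60,3,7.81,0.17,3
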