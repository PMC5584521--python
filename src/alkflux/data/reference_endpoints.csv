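initial_sulfate_mM,hexadecane_consumed_mmol,hexadecane_consumed_se,sulfate_consumed_mmol,sulfate_consumed_se,methane_mmol,methane_se,recovery_pct,recovery_se,mu_max_per_month,mu_max_se,combined_ratio,combined_ratio_se
0.5,0.27,0.05,0.08,0.01,2.86,0.02,91.7,17.3,0.41,0.005,11.23,2.12
2,0.29,0.03,0.19,0.08,2.71,0.01,82.1,7.5,0.27,0.08,10.06,0.92
4,0.29,0.06,0.67,0.01,2.48,0.49,89.7,5.1,0.30,0.09,10.99,0.63
10,0.27,0.05,1.62,0.10,1.61,0.24,101.0,9.7,0.23,0.04,12.37,1.18
15,0.31,0.01,1.95,0.08,1.68,0.13,96.9,5.5,0.22,0.02,11.87,0.67
25,0.33,0.01,2.66,0.11,1.27,0.04,98.1,3.6,0.20,0.02,12.01,0.45
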