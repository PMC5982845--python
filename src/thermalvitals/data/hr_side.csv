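# Per-subject heart-rate validation, side view (n = 16):
# thermal-imaging estimate vs PPG reference.
# Rates in beats/min; eps columns dimensionless.
subject_id,mean_gt,mean_irt,rmse,eps_mean,eps90
1,66.69,66.81,2.87,0.04,0.06
2,63.98,64.48,1.22,0.02,0.03
4,62.11,65.84,5.77,0.06,0.13
6,87.86,85.58,4.35,0.03,0.07
7,70.03,68.72,2.24,0.03,0.05
8,65.97,66.21,3.84,0.04,0.09
9,78.77,76.81,3.95,0.04,0.08
11,65.47,68.13,6.94,0.06,0.12
12,69.82,69.51,3.71,0.04,0.08
13,54.03,52.97,2.54,0.04,0.09
14,64.36,64.86,1.08,0.01,0.02
15,88.98,86.98,4.36,0.04,0.08
16,60.02,63.99,5.18,0.07,0.14
17,65.79,66.16,1.39,0.02,0.04
18,51.08,49.43,2.68,0.04,0.10
19,61.32,63.33,2.72,0.03,0.07
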