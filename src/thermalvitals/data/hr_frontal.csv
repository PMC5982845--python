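# Per-subject heart-rate validation, frontal view (n = 18):
# thermal-imaging estimate vs PPG reference.
# Rates in beats/min; eps columns dimensionless.
subject_id,mean_gt,mean_irt,rmse,eps_mean,eps90
1,72.29,71.21,4.15,0.05,0.11
2,63.26,64.37,2.20,0.03,0.06
3,74.48,73.44,1.91,0.02,0.04
4,63.54,63.98,1.80,0.02,0.05
5,63.68,67.25,4.40,0.06,0.09
6,90.46,85.22,7.16,0.07,0.14
7,73.62,73.83,3.84,0.04,0.08
9,80.46,77.65,4.46,0.05,0.10
11,68.84,69.76,2.17,0.02,0.05
12,66.79,68.06,4.66,0.06,0.11
13,55.50,53.67,5.32,0.09,0.02
14,63.33,63.91,1.13,0.01,0.03
15,93.80,92.88,1.40,0.01,0.02
16,63.54,64.65,4.07,0.05,0.11
17,66.29,66.98,3.34,0.04,0.09
18,54.07,52.10,3.49,0.06,0.10
19,59.28,59.36,3.04,0.04,0.08
20,61.05,62.80,5.01,0.05,0.11
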