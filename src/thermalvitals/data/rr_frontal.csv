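# Per-subject respiratory-rate validation, frontal view (n = 16):
# thermal-imaging estimate vs piezoplethysmography reference.
# Rates in breaths/min; eps columns dimensionless.
subject_id,mean_gt,mean_irt,rmse,eps_mean,eps90
1,13.94,13.51,1.28,0.07,0.13
3,15.46,15.34,0.46,0.02,0.05
4,15.52,15.15,0.96,0.05,0.09
5,13.10,13.16,0.59,0.03,0.08
6,20.62,20.73,0.57,0.02,0.06
7,9.04,9.10,0.24,0.02,0.05
8,12.78,12.43,0.62,0.03,0.05
9,14.21,14.13,0.58,0.03,0.06
10,18.15,17.77,1.13,0.05,0.11
11,19.39,19.43,0.70,0.03,0.05
12,9.70,9.62,0.77,0.05,0.14
14,8.79,9.10,0.81,0.05,0.10
16,17.33,17.26,1.52,0.07,0.15
17,19.33,19.57,0.74,0.03,0.07
18,21.20,21.09,0.48,0.02,0.04
20,15.71,15.81,0.47,0.02,0.04
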