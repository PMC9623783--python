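trait,dg,b0_male,b0_female,b1_male,b1_female,r2_male,r2_female,mean_male,mean_female,max_male,max_female
Stature,1.55,1.70,1.60,1.01,1.00,0.962,0.953,1.71,1.60,2.39,2.42
Strength,0.71,0.85,0.80,0.97,0.97,0.965,0.960,0.85,0.80,1.46,1.48
Body depth,0.88,1.14,1.05,0.98,0.98,0.958,0.953,1.13,1.05,1.75,1.76
Dairy form,1.18,1.81,1.66,1.00,0.99,0.937,0.928,1.81,1.66,2.51,2.48
Rump angle,-0.02,-0.05,-0.03,0.95,0.95,0.971,0.969,0.11,0.11,0.62,0.73
Rump width,1.11,1.25,1.17,0.98,0.98,0.964,0.958,1.24,1.17,1.86,1.84
Rear legs side view,-0.02,0.02,0.01,0.95,0.96,0.977,0.974,0.09,0.09,0.57,0.61
Foot angle,1.17,1.34,1.25,1.00,1.01,0.953,0.945,1.34,1.25,1.85,1.88
Fore attachment,2.10,2.22,2.11,1.03,1.03,0.959,0.947,2.24,2.12,2.83,2.87
Rear udder height,2.19,2.38,2.27,1.05,1.05,0.959,0.943,2.42,2.29,3.01,3.03
Rear udder width,2.00,2.41,2.28,1.06,1.05,0.951,0.931,2.45,2.30,3.04,3.10
Udder cleft,1.31,1.59,1.52,0.99,0.98,0.955,0.949,1.59,1.51,2.13,2.17
Udder depth,1.51,1.35,1.29,0.98,0.99,0.966,0.960,1.34,1.29,1.90,2.01
Front teat placement,1.20,1.43,1.35,0.98,0.98,0.951,0.946,1.39,1.33,1.96,2.08
Teat length,-0.21,-0.18,-0.18,0.94,0.95,0.973,0.969,0.18,0.19,0.91,0.93
Rear legs rear view,1.00,1.24,1.15,1.00,1.00,0.946,0.932,1.24,1.15,1.75,1.78
Feet and legs,1.25,1.45,1.35,1.05,1.04,0.926,0.905,1.47,1.36,1.95,2.01
Rear teat placement,1.07,1.29,1.22,0.97,0.97,0.960,0.956,1.28,1.21,1.81,1.86
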