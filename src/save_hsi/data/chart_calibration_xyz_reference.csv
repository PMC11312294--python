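patch_id,before_X,before_Y,before_Z,after_X,after_Y,after_Z,rmse_reported,sd_reported
1,10.96,9.92,4.63,11.14,9.87,4.26,0.24,0.30
2,38.74,35.80,18.65,38.57,35.94,18.66,0.13,0.08
3,16.62,19.07,24.13,16.48,18.79,24.11,0.18,0.17
4,10.33,12.86,4.62,10.16,13.03,4.85,0.19,0.19
5,24.05,23.87,31.55,24.16,24.07,31.60,0.13,0.08
6,30.12,42.15,32.40,30.10,42.17,32.42,0.02,0.002
7,38.10,30.24,4.28,38.04,30.37,4.22,0.09,0.04
8,11.70,11.47,25.90,11.64,11.37,25.91,0.07,0.02
9,29.01,19.91,9.62,29.20,19.78,9.60,0.13,0.08
10,8.26,6.49,9.63,8.06,6.49,9.86,0.18,0.17
11,34.15,44.06,8.44,34.15,44.02,8.53,0.06,0.01
12,47.99,44.55,6.05,48.05,44.34,6.17,0.15,0.11
13,6.82,5.79,21.07,6.90,5.91,21.00,0.09,0.04
14,14.55,23.55,7.22,14.58,23.51,7.12,0.07,0.02
15,21.08,12.25,3.57,21.01,12.28,3.65,0.06,0.01
16,58.40,60.69,7.54,58.38,60.79,7.42,0.09,0.04
17,28.98,19.54,20.67,28.94,19.52,20.66,0.02,0.002
18,12.81,19.01,28.54,12.84,19.10,28.56,0.05,0.01
19,82.12,88.54,67.20,82.31,88.73,67.51,0.24,0.30
20,54.74,58.92,45.52,54.28,58.40,44.75,0.60,1.89
21,33.08,35.73,27.24,33.26,35.82,27.54,0.21,0.23
22,18.18,19.62,14.94,18.86,20.31,15.62,0.68,2.43
23,9.13,10.01,8.13,8.56,9.26,7.21,0.76,3.04
24,2.87,3.19,2.39,3.10,3.35,2.68,0.23,0.27
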