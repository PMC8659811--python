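group,exam,CYFRA21-1,CEA,CA-125,NSE,CA242,PSA,HGH,Free-PSA,FERRITIN
1,1,36.71,3.29,157.64,21,31,0.81,0.51,1.88,154.2
1,2,33.58,4.12,189.55,16,24,1.01,0.82,1.45,189.6
1,3,40.23,3.15,156.31,27,32,0.95,0.77,1.78,175.8
1,4,31.84,3.92,179.32,22,28,1.45,0.48,0.81,193.7
1,5,34.53,3.44,198.09,19,31,0.98,0.89,0.57,173.8
2,1,1.20,75.48,576.12,33,9,1.22,11.25,21.88,935.7
2,2,1.15,82.79,498.32,37,5,1.48,22.82,28.74,854.1
2,3,0.91,79.32,524.89,22,6,1.88,19.85,24.32,718.2
2,4,1.01,89.11,489.36,24,7,0.99,23.58,26.81,921.5
2,5,1.03,84.12,518.88,27,4,1.57,18.78,37.58,814.6
3,1,1.22,6.77,116.32,31,21,7.22,6.51,0.12,258.9
3,2,1.41,8.24,97.54,36,26,7.52,5.32,0.55,322.7
3,3,1.32,16.78,104.58,35,29,7.14,4.87,0.17,278.9
3,4,1.20,22.12,99.28,28,24,8.56,5.99,0.45,341.8
3,5,1.19,17.95,89.65,21,22,8.47,6.02,0.67,304.8
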