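exam_index,CYFRA21-1,CEA,CA-125,NSE,CA242,PSA,HGH,Free-PSA,FERRITIN
1,4.16,285.41,711.01,34,8,1.12,10.25,58.81,835.7
2,5.57,277.99,688.81,36,5,1.42,11.21,49.71,754.1
3,3.55,257.15,521.42,27,6,1.86,12.15,48.22,738.2
4,4.28,231.44,461.56,25,6,1.29,11.20,47.55,622.1
5,3.47,184.88,408.18,36,5,1.54,15.71,38.51,422.6
6,4.84,128.11,321.88,27,7,1.68,13.88,35.12,351.8
7,5.17,62.89,295.10,38,6,1.71,12.51,11.6,211.1
8,3.89,21.17,178.20,21,5,1.55,13.61,7.1,209.7
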