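percentile,stature_m,body_mass_kg,neck_circumference_cm,neck_length_cm
1,1.48,46.4,29.1,7.9
5,1.53,51.3,30.2,8.7
10,1.55,54.6,30.7,9.1
20,1.58,58.5,31.3,9.6
30,1.60,61.6,31.9,10.0
40,1.61,64.5,32.4,10.3
50,1.63,66.8,32.8,10.6
60,1.64,69.5,33.3,10.9
70,1.66,72.6,33.8,11.3
80,1.68,76.4,34.5,11.6
90,1.71,82.4,35.5,12.2
95,1.74,87.1,36.3,12.7
99,1.78,98.3,38.5,13.6
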