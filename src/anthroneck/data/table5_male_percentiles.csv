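percentile,stature_m,body_mass_kg,neck_circumference_cm,neck_length_cm
1,1.60,57.8,34.6,8.0
5,1.65,64.4,36.0,8.7
10,1.67,68.2,36.7,9.2
20,1.70,73.4,37.5,9.7
30,1.72,77.4,38.3,10.1
40,1.74,81.0,38.9,10.4
50,1.76,84.6,39.5,10.8
60,1.77,88.0,40.2,11.1
70,1.79,92.0,41.0,11.4
80,1.81,96.6,41.8,11.8
90,1.84,104.4,43.2,12.4
95,1.87,110.7,44.3,12.9
99,1.93,124.7,46.8,13.8
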