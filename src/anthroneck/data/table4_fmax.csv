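name,original_N,optimized_male_N,optimized_female_N
stern_mast,86.1,221.58,88.4
cleid_mast,43.1,123.3,44.5
cleid_occ,43.1,123.3,43.0
scalenus_ant,65.8,74.07,65.2
scalenus_med,65.8,77.77,60.2
scalenus_post,36.8,43.47,37.3
long_cap_sklc4,48.0,123.57,50.8
long_col_c1thx,14.4,41.2,19.2
long_col_c1c5,14.4,41.2,20.4
long_col_c5thx,14.4,41.2,11.8
trap_cl,132.0,155.93,122.3
trap_acr,348.6,411.83,327.8
splen_cap_sklc6,55.0,65.02,44.1
splen_cap_sklthx,53.2,62.84,48.4
splen_cerv_c3thx,50.1,59.16,29.8
semi_cap_sklc5,91.7,108.3,74.8
semi_cap_sklthx,101.5,119.92,77.2
levator_scap,109.2,128.99,99.5
longissi_cap_sklc6,34.3,40.54,31.0
longissi_cerv_c4thx,52.2,61.71,41.1
iliocost_cerv_c5rib,36.4,43.0,34.7
rectcap_post_maj,58.8,69.46,38.4
rectcap_post_min,32.2,46.55,29.3
obl_cap_sup,30.8,40.02,25.8
obl_cap_inf,68.3,80.70,50.5
omohyoid,26.3,75.2,26.5
sternohyoid,20.3,58.1,21.1
sternothyroid,22.8,65.2,23.4
semi_cerv_c3thx,107.1,126.54,102.5
supmult-C4/5-C2,14.7,17.39,9.7
supmult-C5/6-C2,19.3,22.77,17.6
supmult-C6/7-C2,15.8,18.71,14.0
supmult-T1-C4,16.3,19.28,10.8
supmult-T1-C5,11.7,13.80,8.8
supmult-T2-C6,6.5,7.65,3.9
deepmult-C4/5-C2,7.4,8.79,4.4
deepmult-C5/6-C3,12.3,14.55,9.6
deepmult-C6/7-C4,16.1,18.99,9.5
deepmult-T1-C5,12.3,14.55,7.5
deepmult-T1-C6,8.3,9.83,7.7
deepmult-T2-C7,14.0,16.54,9.1
deepmult-T2-T1,14.0,16.54,9.1
rectcap_ant,,92.6,60.19
rectcap_lat,,92.6,60.19
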