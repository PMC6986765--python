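row,extension_N,flexion_N,lateral_bending_N,axial_rotation_Nm
original_model,255,66,109,7.4
male_target,254,122,173,11.2
male_optimized,248,119,190,11.5
male_difference_pct,-2.4,-2.5,9.8,2.7
female_target,165,79.6,112.3,7.3
female_optimized,171,78,103,7.3
female_difference_pct,4.0,-2,-8.3,0
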