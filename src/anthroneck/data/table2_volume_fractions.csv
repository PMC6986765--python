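group,female_pct,male_pct,average_pct
sternocleidomastoid,17.3,14.0,15.0
scalenus,6.4,6.3,6.3
longus_capitis,2.4,1.6,1.8
longus_colli,1.9,1.7,1.7
trapezius,25.9,28.7,27.9
splenius,9.3,9.9,9.7
semispinalis_capitis,10.6,10.7,10.7
semispinalis_cervicis_multifidus,8.7,7.0,7.5
longissimus_capitis,1.5,1.8,1.7
longissimus_cervicis,1.1,1.3,1.2
levator_scapulae,8.9,10.0,9.7
rectus_capitis_major,0.8,0.8,0.8
rectus_capitis_minor,0.3,1.1,0.9
obliquus_capitis_superior,0.3,0.6,0.5
obliquus_capitis_inferior,1.4,1.9,1.8
infrahyoid,3.4,2.7,2.9
total_volume_cm3,510.4,813.9,
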