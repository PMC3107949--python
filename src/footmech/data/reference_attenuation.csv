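structure,damage_stage,fraction_removed,flatfoot_stiffness_N_per_mm
spring_superomedial,IV,7/8,39
spring_inferomedial,II,3/8,94
talocalcaneal_interosseous,I,1/8,236
plantar_fascia,I,1/8,175
plantar_metatarsocuneiform,0,0,90
plantar_naviculocuneiform,0,0,180
long_and_short_plantar,0,0,240
deltoid_deep,0,0,200
deltoid_superficial_anterior,I,1/8,70
deltoid_superficial_posterior,0,0,117
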