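band,normal,flatfoot,mco,evans,ccda,evans_mco,ccda_mco
long_plantar_1,1.0,2.8,2.1,2.4,2.1,1.9,1.4
long_plantar_2,1.0,2.8,2.5,2.7,2.3,2.2,2.2
long_plantar_3,1.5,2.8,2.5,3.0,2.5,2.7,2.0
long_plantar_4,1.8,2.3,3.1,3.4,2.9,3.3,2.2
long_plantar_5,1.7,2.9,2.7,3.5,2.9,3.5,2.6
long_plantar_6,1.8,2.7,3.0,3.9,3.2,4.0,3.2
long_plantar_7,0.6,1.2,2.1,2.7,2.0,3.5,3.1
long_plantar_8,1.7,1.7,5.3,4.1,4.0,5.6,6.0
plantar_fascia_1,3.9,7.2,3.4,2.5,2.0,1.6,0.4
plantar_fascia_2,2.1,4.3,2.1,2.2,1.8,1.2,0.5
plantar_fascia_3,2.7,4.5,3.5,3.5,3.3,2.5,1.5
plantar_fascia_4,2.7,4.0,3.6,4.7,4.1,5.1,3.8
plantar_fascia_5,3.2,3.7,4.2,4.7,4.7,4.7,4.8
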