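angle,normal,flatfoot,mco,evans,ccda,evans_mco,ccda_mco
l_t1mt,0.5,-8.6,-3.7,2.9,6.8,1.2,0.8
l_tc,39.4,41.0,37.9,43.2,37.5,41.3,35.8
l_cp,16.6,14.0,13.1,19.5,15.7,17.0,13.7
ap_t1mt,7.2,-1.7,7.2,11.9,16.8,13.5,20.5
ap_tn,-7.0,-8.9,-6.5,2.4,-2.4,3.5,-0.4
hindfoot,93.4,96.4,87.7,94.7,93.1,90.9,86.9
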