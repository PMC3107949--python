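region,normal,flatfoot,mco,evans,ccda,evans_mco,ccda_mco
ray1,116,125,58,38,18,8,0
ray2,8,16,2,6,9,4,0
ray3,40,36,23,38,47,25,26
ray4,24,30,79,52,49,56,53
ray5,61,60,117,122,133,160,177
calcaneus,428,422,410,431,448,443,441
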