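participant,full,mtl,hpc,amy,phc,ent,pfc,acc
P1,48,24,8,0,16,0,8,8
P2,64,32,16,0,8,8,16,8
P3,72,24,16,8,0,0,24,8
P4,40,40,16,8,8,8,0,0
P5,72,32,16,16,0,0,24,16
P6,80,48,16,16,8,8,8,8
P7,72,48,16,16,0,16,8,16
P8,40,16,8,0,8,0,16,0
P9,96,24,0,8,0,16,8,16
P10,96,40,24,8,0,8,24,0
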