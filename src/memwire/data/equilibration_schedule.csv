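step,length_ns,backbone_restraint,sidechain_restraint,other_restraint,thermostat,barostat
1,,4000,4000,400,,
2,0.1,4000,4000,400,Berendsen,
3,0.1,4000,4000,400,Berendsen,Berendsen
4,0.1,2000,2000,80,Berendsen,Berendsen
5,0.1,2000,2000,16,Berendsen,Berendsen
6,20,2000,2000,0,Berendsen,Berendsen
7,2,2000,1000,0,Berendsen,Berendsen
8,2,2000,400,0,Berendsen,Berendsen
9,2,1000,400,0,Berendsen,Berendsen
10,2,400,200,0,Berendsen,Berendsen
11,2,200,20,0,Berendsen,Berendsen
12,10,20,0,0,Berendsen,Berendsen
13,20,0,0,0,v-rescale,c-rescale
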