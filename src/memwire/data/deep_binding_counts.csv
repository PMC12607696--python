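site,AA_AAC1,AA_UCP1,POPC_AAC1,POPC_UCP1
TM1/TM2,5,0,8,0
TM3/TM4,2,1,0,0
TM5/TM6,4,5,6,7
TM6/TM1,0,0,4,0
IMS cavity,3,0,0,0
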