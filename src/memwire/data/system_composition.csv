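molecule,charge_e,count_AAC1,count_UCP1
protein,,1,1
tetralinoleoylcardiolipin,-2,3,3
POPC,0,211,217
arachidonate,-1,16,16
water,0,14375,14595
potassium,1,41,49
chloride,-1,38,38
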