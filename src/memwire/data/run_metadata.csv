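protein,run,timestep_fs,save_interval_ps,saved_frames,time_us
AAC1,1,4,200,35242,7.0484
AAC1,2,4,200,35336,7.0672
AAC1,3,2,100,58325,5.8325
AAC1,4,2,100,58169,5.8169
AAC1,5,4,200,25043,5.0086
AAC1,6,4,200,37351,7.4702
UCP1,1,4,200,37084,7.4168
UCP1,2,4,200,36265,7.253
UCP1,3,2,100,55026,5.5026
UCP1,4,2,100,48309,4.8309
UCP1,5,4,200,32256,6.4512
UCP1,6,4,200,29577,5.9154
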