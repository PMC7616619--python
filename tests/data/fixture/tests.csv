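patient_id,test_type,date
p0,FBC,2020-02-20
p0,LFT,2020-02-20
p0,UE,2020-02-20
p0,FBC,2020-05-20
p0,LFT,2020-05-20
p0,UE,2020-05-20
p2,FBC,2020-02-20
p2,LFT,2020-02-20
p2,UE,2020-02-20
p2,FBC,2020-05-20
p2,LFT,2020-05-20
p2,UE,2020-05-20
p4,FBC,2020-02-20
p4,LFT,2020-02-20
p4,UE,2020-02-20
p4,FBC,2020-05-20
p4,LFT,2020-05-20
p4,UE,2020-05-20
p6,FBC,2020-02-20
p6,LFT,2020-02-20
p6,UE,2020-02-20
p6,FBC,2020-05-20
p6,LFT,2020-05-20
p6,UE,2020-05-20
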