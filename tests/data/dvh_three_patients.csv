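patient_id,dose_gy,volume,volume_unit
P1,0,1.0,fraction
P1,40,0.4,fraction
P1,80,0.0,fraction
P2,0,100,percent
P2,30,60,percent
P2,60,10,percent
P2,75,0,percent
P3,0,250,cc
P3,20,200,cc
P3,50,100,cc
P3,70,25,cc
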