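patient_id,grade,age,psa,gleason_group,prescribed_dose_gy
P1,0,71,8.2,2,80
P2,2,66,12.5,3,80
P3,1,75,5.1,1,72
P4,0,80,9.0,2,80
Q1,1,69,7.7,2,80
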