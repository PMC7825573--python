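patient_id,dose_gy,volume,volume_unit
Q1,0,1.0,fraction
Q1,50,0.5,fraction
Q1,30,0.8,fraction
Q1,70,0.1,fraction
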