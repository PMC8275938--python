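case_id,contusion_ais,MPS,DDM
3,4,0.556,0
6,2,2.457,0.020488625
8,3,1.181,0.043110134
9,2,0.818,0.000129266
11,3,0.934,0.000129266
12,5,1.833,0.032445708
22,2,1.092,0.018420372
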