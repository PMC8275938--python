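case_id,dai_ais,CSDM_0.15,CSDM_0.25,MPS
1,2,0.98991727,0.850504137,0.881
2,1,0.82348759,0.389154602,0.603
3,3,0.840098242,0.362849018,0.556
4,0,0.998771975,0.942735264,1.29
5,2,0.997608583,0.916041882,1.019
6,3,0.998061013,0.990951396,2.457
7,4,0.999224405,0.944738883,2.32
15,4,0.993148914,0.985780765,1.402
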