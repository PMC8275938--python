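case_id,dai_ais,contusion_ais,mais
1,2,,2
2,1,,1
3,3,4,4
4,0,,0
5,2,,2
6,3,2,3
7,4,,4
8,,3,4
9,,2,2
10,,,4
11,,3,3
12,,5,5
13,,,5
14,,,1
15,4,,4
16,,,1
17,,,5
18,,,6
19,,,0
20,,,0
21,,,1
22,,2,2
23,,,6
24,,,1
25,,,2
26,,,6
27,,,1
28,,,1
29,,,6
30,,,5
31,,,5
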