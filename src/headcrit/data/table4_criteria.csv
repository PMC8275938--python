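case_id,HIC,GAMBIT,BrIC,RIC,HIP
1,780.02,4.33,4.45,189537000,4.88
2,184.69,1.73,1.95,54634500,6.29
3,1586.97,3.30,3.60,136134000,4.56
4,1031.01,5.15,5.37,249415000,20.19
5,2939.93,2.09,2.25,48786900,15.80
6,1391.30,6.33,6.55,379812000,4.22
7,3833.51,10.11,10.09,350811000,10.00
8,2051.95,11.14,11.36,385087000,19.64
9,699.90,1.89,2.00,73385300,11.97
10,1288.22,4.54,4.73,208250000,14.04
11,3569.25,9.12,9.35,653978000,15.41
12,3395.78,8.60,8.72,619131000,22.46
13,2369.58,9.94,9.94,845224000,6.55
14,2503.95,2.89,2.94,244043000,4.39
15,1499.24,1.78,2.35,160381000,14.43
16,772.20,2.45,2.73,38496500,2.73
17,1533.34,2.23,2.23,142236000,7.53
18,8107.39,5.26,5.53,625871900,19.88
19,197.54,0.72,0.91,9397440,5.07
20,254.16,1.80,1.84,13210200,6.62
21,311.20,0.99,1.09,6189740,8.17
22,1205.82,3.53,3.94,271328000,4.16
23,9256.10,6.29,6.36,710420000,16.89
24,1757.95,6.57,6.60,453202000,21.64
25,678.03,0.77,0.63,3555080,1.51
26,7249.62,5.93,5.91,437064000,28.70
27,883.26,2.11,2.26,175018000,7.88
28,3365.14,9.04,9.07,786648000,4.79
29,1423.95,2.46,2.92,152093000,11.26
30,2013.30,4.29,4.42,146262000,13.69
31,1411.30,1.74,1.95,59559500,5.68
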