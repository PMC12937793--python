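test,Uin_V,Uoff_V,Vpp_mV,Vavg_mV
1,4.910,3.520,383.00,41
2,4.917,3.521,383.03,48
3,4.920,3.522,383.02,49
4,4.924,3.523,383.03,51
5,4.931,3.524,383.04,55
6,4.930,3.525,383.05,58
7,4.938,3.526,383.06,61
8,4.945,3.527,383.07,64
9,4.940,3.528,383.08,67
10,4.952,3.530,383.09,69
11,4.959,3.531,383.10,71
12,4.950,3.532,383.11,72
13,4.966,3.533,383.12,73
14,4.967,3.560,383.30,74
15,4.924,3.552,457.60,84
16,4.931,3.557,567.23,99
17,4.930,3.562,879.40,120
18,4.938,3.567,973.57,146
19,4.945,3.571,1007.68,150
20,4.940,3.576,1340.21,167
21,4.952,3.581,1420.79,175
22,4.959,3.586,1457.93,189
23,4.950,3.590,1789.17,199
24,4.966,3.595,1934.55,202
25,4.973,3.600,2346.67,211
26,4.960,3.605,2584.50,218
27,4.968,3.610,2865.70,234
28,4.969,3.614,3146.90,245
29,4.988,3.619,3428.19,257
30,4.995,3.624,3709.35,267
31,4.940,3.629,3990.57,288
32,4.952,3.633,4991.78,321
33,5.020,3.640,4020.31,353
34,5.005,3.742,5670.35,345
35,6.015,3.847,6320.89,361
36,6.025,3.851,7270.67,377
37,6.035,3.956,7620.98,393
38,6.070,4.350,7710.04,490
39,7.510,5.310,19800.89,2080
40,7.532,5.421,32190.56,2670
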