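age_start,q_annual,disability_weight
0,0.0140400422883,0.035
1,0.00140400422883,0.038
5,0.00042120126865,0.04
10,0.00042120126865,0.04
15,0.000702002114416,0.055
20,0.000702002114416,0.06
25,0.000702002114416,0.065
30,0.00105300317162,0.075
35,0.00165143770542,0.085
40,0.00258996987698,0.095
45,0.00406188131813,0.105
50,0.00637029796723,0.12
55,0.00999061592722,0.135
60,0.0156684046992,0.155
65,0.024572950017,0.18
70,0.038538056945,0.21
75,0.060439704312,0.235
80,0.0947883247599,0.255
85,0.148657684763,0.27
90,0.233141658481,0.28
95,0.365638903941,0.29
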