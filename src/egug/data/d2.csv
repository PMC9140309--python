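value
65
156
100
134
16
108
121
4
39
143
56
26
22
1
1
5
65
56
65
17
7
16
22
3
4
2
8
4
3
30
4
43
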