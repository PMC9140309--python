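value
1277
1290
1357
1369
1408
1455
1478
1549
115
181
255
418
441
461
516
739
743
789
807
865
924
983
1024
1062
1063
1165
1191
1222
1222
1251
1578
1578
1599
1603
1605
1696
1735
1799
1815
1852
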