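value
840
157
145
44
33
121
150
280
434
736
584
887
263
1901
695
294
562
721
40
1336
335
1354
454
139
780
203
436
30
246
1617
638
937
735
76
710
36
667
384
129
46
402
194
40
556
99
9
209
599
38
365
92
82
220
759
304
83
319
375
832
460
567
328
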