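lg	parent_a_cm	parent_b_cm	cross_markers	scaffolds	mb
I	14.9	2.1	7954	2275	63.410
II	72.3	37.2	2582	1278	44.126
III	31.9	59.6	3901	1267.5	42.570
IV	23.4	81.9	4154	1835.5	38.203
V	58.5	20.2	2789	965	36.603
VI	38.3	57.4	5020	1659	33.382
VII	35.1	31.9	3075	1127	29.802
VIII	40.4	54.3	2685	1080	28.083
IX	62.8	48.9	1362	592	26.313
X	7.4	28.7	2930	1190.5	24.348
XI	75.5	39.4	2168	669.5	22.606
XII	73.4	22.3	2144	961	22.396
XIII	59.6	64.9	2197	900.5	22.389
XIV	56.4	35.1	1062	562.5	17.916
XV	29.8	31.9	1263	449.5	17.663
XVI	0	0	1300	621.5	14.697
XVII	37.2	45.7	894	415	12.792
XVIII	21.3	14.9	1307	540.5	12.782
XIX	3.2	0	122	94	1.407
XX	0	0	181	26	1.286
XXI	5.3	0	86	40	1.276
XXII	0	0	11	18.5	0.469
XXIII	0	0	61	33	0.323
XXIV	0	0	5	12	0.210
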