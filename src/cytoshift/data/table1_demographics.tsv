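sample_id	group	age	bmi	volume
003	small	67	24.9	20
004	small	61	25.1	32.7
006	small	74	25.5	17.2
007	small	61	26.6	25
008	small	68	22.6	21
009	small	63	27.2	23.3
010	small	68	27.8	29.5
1144	small	61	26.2	29
013	small	69	27.3	31
1196	small	71	27.2	34
766	large	71	34.4	227.7
012	large	67	26.3	100
1157	large	76	24.3	145
1195	large	63	29	123
1338	large	51	38	140
1344	large	64	33.6	133
0118	large	68	22.5	96.1
1579	large	64	24.7	114
1595	large	73	32.7	335
1652	large	59	29.4	207
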