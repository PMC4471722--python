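group_id	species	chromosome
1	Bd	1
1	Os	3
1	Sb	1
2	Bd	4
2	Os	9
2	Sb	2
3	Bd	4
3	Os	12
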