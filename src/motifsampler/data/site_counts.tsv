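Position	A	C	G	U
1	0	34	0	0
2	0	0	0	34
3	0	0	33	1
4	7	0	26	1
5	29	0	0	5
6	32	0	2	0
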