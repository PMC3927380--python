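Position	A	C	G	U
1	-3.55288	1.34992	-3.55495	-3.55600
2	-3.55288	-3.55757	-3.55495	1.47685
3	-3.55288	-3.55757	1.21665	-1.85463
4	-0.15376	-3.55757	0.98051	-1.85463
5	1.24196	-3.55757	-3.55495	-0.40295
6	1.33962	-3.55757	-1.46340	-3.55600
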