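Position	A	C	G	U
1	0.00691	0.97866	0.00805	0.00638
2	0.00691	0.00723	0.00805	0.97780
3	0.00691	0.00723	0.95091	0.03495
4	0.20691	0.00723	0.75091	0.03495
5	0.83548	0.00723	0.00805	0.14923
6	0.92120	0.00723	0.06519	0.00638
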