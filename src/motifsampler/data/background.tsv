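Code	Count	Freq
A	7622	0.2419
C	7977	0.2532
G	8879	0.2818
U	7031	0.2231
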