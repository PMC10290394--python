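samples	degree	count
A,B,C	3	1
A,B	2	1
B	1	2
A	1	1
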