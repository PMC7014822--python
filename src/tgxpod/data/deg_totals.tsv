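experiment	series	total_degs
A	males_d8	2685
B	males_d8	176
B	females_d8	485
B	males_d29	1110
B	females_d29	1814
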