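endpoint	experiment	series	dose	n	mean	dispersion
ki67	A	males_d8	0	6	5.89	1.01
ki67	A	males_d8	30	6	2.93	0.65
ki67	A	males_d8	100	6	2.56	0.46
ki67	A	males_d8	300	6	4.31	0.70
ki67	A	males_d8	1000	6	24.62	3.58
ki67	B	males_d8	0	6	2.81	1.75
ki67	B	males_d8	300	6	2.42	1.42
ki67	B	males_d8	500	6	3.16	1.42
ki67	B	males_d8	750	6	4.15	1.84
ki67	B	males_d8	1000	6	4.26	1.69
ki67	B	males_d8	1500	6	5.93	1.45
ki67	B	males_d29	0	6	3.14	0.76
ki67	B	males_d29	300	6	2.38	0.75
ki67	B	males_d29	500	6	3.72	0.87
ki67	B	males_d29	750	6	3.87	0.86
ki67	B	males_d29	1000	6	4.19	0.71
ki67	B	males_d29	1500	6	10.31	13.35
ki67	B	females_d8	0	6	1.18	0.44
ki67	B	females_d8	300	6	1.58	1.19
ki67	B	females_d8	500	6	1.87	0.91
ki67	B	females_d8	750	6	3.53	1.74
ki67	B	females_d8	1000	6	3.51	1.75
ki67	B	females_d8	1500	6	2.73	0.64
ki67	B	females_d29	0	6	2.23	0.81
ki67	B	females_d29	300	6	2.66	1.11
ki67	B	females_d29	500	6	2.75	0.64
ki67	B	females_d29	750	6	4.09	0.28
ki67	B	females_d29	1000	6	4.58	1.14
ki67	B	females_d29	1500	6	5.69	0.95
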