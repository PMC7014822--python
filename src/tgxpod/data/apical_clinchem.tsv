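endpoint	experiment	series	dose	n	mean	dispersion
ast	A	males_d8	0	6	76.67	3.88
ast	A	males_d8	30	6	66.17	3.92
ast	A	males_d8	100	6	69.67	1.84
ast	A	males_d8	300	6	78.67	7.02
ast	A	males_d8	1000	6	167.83	25.70
ast	B	males_d8	0	6	79.17	2.30
ast	B	males_d8	300	6	73.83	4.81
ast	B	males_d8	500	6	77.00	1.44
ast	B	males_d8	750	6	78.00	2.21
ast	B	males_d8	1000	6	80.67	4.45
ast	B	males_d8	1500	6	99.67	4.70
ast	B	males_d29	0	6	74.67	4.36
ast	B	males_d29	300	6	74.50	5.25
ast	B	males_d29	500	6	77.33	5.45
ast	B	males_d29	750	6	63.33	3.78
ast	B	males_d29	1000	6	93.00	8.72
ast	B	males_d29	1500	6	96.67	14.79
ast	B	females_d8	0	6	83.17	3.50
ast	B	females_d8	300	6	90.83	1.83
ast	B	females_d8	500	6	94.33	9.05
ast	B	females_d8	750	6	88.00	3.70
ast	B	females_d8	1000	6	101.00	6.85
ast	B	females_d8	1500	6	95.67	2.82
ast	B	females_d29	0	6	80.50	5.18
ast	B	females_d29	300	6	79.17	4.71
ast	B	females_d29	500	6	87.00	9.37
ast	B	females_d29	750	6	101.17	16.68
ast	B	females_d29	1000	6	93.67	6.23
ast	B	females_d29	1500	6	136.83	30.32
alt	A	males_d8	0	6	57.00	4.46
alt	A	males_d8	30	6	56.67	3.84
alt	A	males_d8	100	6	52.83	4.19
alt	A	males_d8	300	6	58.83	4.45
alt	A	males_d8	1000	6	114.67	12.94
alt	B	males_d8	0	6	42.83	2.23
alt	B	males_d8	300	6	43.00	5.47
alt	B	males_d8	500	6	47.50	2.70
alt	B	males_d8	750	6	52.67	3.30
alt	B	males_d8	1000	6	55.00	6.77
alt	B	males_d8	1500	6	55.67	5.71
alt	B	males_d29	0	6	44.00	2.41
alt	B	males_d29	300	6	43.33	1.58
alt	B	males_d29	500	6	47.50	2.26
alt	B	males_d29	750	6	41.33	2.29
alt	B	males_d29	1000	6	55.17	6.33
alt	B	males_d29	1500	6	63.33	8.77
alt	B	females_d8	0	6	40.67	1.38
alt	B	females_d8	300	6	40.67	2.63
alt	B	females_d8	500	6	41.67	2.56
alt	B	females_d8	750	6	43.83	2.33
alt	B	females_d8	1000	6	51.17	2.56
alt	B	females_d8	1500	6	55.33	4.32
alt	B	females_d29	0	6	41.67	3.68
alt	B	females_d29	300	6	36.83	2.02
alt	B	females_d29	500	6	38.00	2.52
alt	B	females_d29	750	6	44.00	2.46
alt	B	females_d29	1000	6	47.83	3.77
alt	B	females_d29	1500	6	86.67	31.79
tbil	B	males_d8	0	6	2.94	0.18
tbil	B	males_d8	300	6	2.92	0.24
tbil	B	males_d8	500	6	3.18	0.14
tbil	B	males_d8	750	6	2.92	0.25
tbil	B	males_d8	1000	6	2.73	0.39
tbil	B	males_d8	1500	6	2.99	0.23
tbil	B	males_d29	0	6	2.24	0.27
tbil	B	males_d29	300	6	2.25	0.28
tbil	B	males_d29	500	6	2.88	0.38
tbil	B	males_d29	750	6	2.89	0.30
tbil	B	males_d29	1000	6	3.03	0.34
tbil	B	males_d29	1500	6	3.62	0.85
tbil	B	females_d8	0	6	2.80	0.14
tbil	B	females_d8	300	6	3.25	0.49
tbil	B	females_d8	500	6	3.49	0.29
tbil	B	females_d8	750	6	3.16	0.31
tbil	B	females_d8	1000	6	2.90	0.37
tbil	B	females_d8	1500	6	2.91	0.22
tbil	B	females_d29	0	6	2.55	0.18
tbil	B	females_d29	300	6	3.04	0.33
tbil	B	females_d29	500	6	3.27	0.47
tbil	B	females_d29	750	6	3.59	0.48
tbil	B	females_d29	1000	6	3.61	0.22
tbil	B	females_d29	1500	6	4.88	1.00
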