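experiment	series	direction	dose	count
A	males_d8	up	30	0
A	males_d8	up	100	0
A	males_d8	up	300	1
A	males_d8	up	1000	1717
A	males_d8	down	30	0
A	males_d8	down	100	0
A	males_d8	down	300	0
A	males_d8	down	1000	968
B	males_d8	up	300	0
B	males_d8	up	500	0
B	males_d8	up	750	0
B	males_d8	up	1000	0
B	males_d8	up	1500	129
B	males_d8	down	300	0
B	males_d8	down	500	1
B	males_d8	down	750	0
B	males_d8	down	1000	0
B	males_d8	down	1500	4
B	males_d29	up	300	1
B	males_d29	up	500	16
B	males_d29	up	750	22
B	males_d29	up	1000	22
B	males_d29	up	1500	394
B	males_d29	down	300	1
B	males_d29	down	500	2
B	males_d29	down	750	12
B	males_d29	down	1000	37
B	males_d29	down	1500	418
B	females_d8	up	300	0
B	females_d8	up	500	6
B	females_d8	up	750	146
B	females_d8	up	1000	167
B	females_d8	up	1500	926
B	females_d8	down	300	1
B	females_d8	down	500	1
B	females_d8	down	750	7
B	females_d8	down	1000	9
B	females_d8	down	1500	80
B	females_d29	up	300	0
B	females_d29	up	500	52
B	females_d29	up	750	109
B	females_d29	up	1000	352
B	females_d29	up	1500	1202
B	females_d29	down	300	0
B	females_d29	down	500	6
B	females_d29	down	750	48
B	females_d29	down	1000	109
B	females_d29	down	1500	478
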