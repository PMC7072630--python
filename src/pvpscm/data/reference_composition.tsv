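amino_acid	positive_pct	negative_pct	printed_difference	printed_rank
A	9.98	8.09	1.89	1
C	0.66	1.05	-0.39	14
D	5.23	5.87	-0.64	16
E	4.85	7.36	-2.51	19
F	3.91	3.91	0.00	10
G	8.20	6.42	1.78	2
H	1.04	1.80	-0.76	17
I	6.23	6.06	0.17	8
K	5.14	7.81	-2.67	20
L	7.80	8.34	-0.54	15
M	2.64	2.73	-0.09	11
N	4.69	4.64	0.05	9
P	4.13	3.76	0.38	7
Q	4.18	3.72	0.46	6
R	4.28	5.48	-1.21	18
S	7.29	6.10	1.19	5
T	6.90	5.49	1.41	4
V	8.09	6.39	1.71	3
W	1.38	1.50	-0.12	12
Y	3.37	3.50	-0.12	13
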