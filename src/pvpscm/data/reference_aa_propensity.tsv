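amino_acid	propensity	printed_rank
A	529.50	1
C	426.58	13
D	435.45	12
E	358.93	19
F	423.45	15
G	506.68	4
H	378.45	18
I	443.18	10
K	310.90	20
L	395.85	16
M	426.15	14
N	471.50	7
P	462.15	8
Q	452.83	9
R	383.15	17
S	504.63	5
T	511.43	2
V	506.88	3
W	442.33	11
Y	479.13	6
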