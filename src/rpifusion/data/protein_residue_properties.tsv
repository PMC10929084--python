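unit	hydrophobicity	hydrophilicity	mass
A	1.8	-0.5	71.08
C	2.5	-1	103.14
D	-3.5	3	115.09
E	-3.5	3	129.12
F	2.8	-2.5	147.18
G	-0.4	0	57.05
H	-3.2	-0.5	137.14
I	4.5	-1.8	113.16
K	-3.9	3	128.17
L	3.8	-1.8	113.16
M	1.9	-1.3	131.19
N	-3.5	0.2	114.1
P	-1.6	0	97.12
Q	-3.5	0.2	128.13
R	-4.5	3	156.19
S	-0.8	0.3	87.08
T	-0.7	-0.4	101.1
V	4.2	-1.5	99.13
W	-0.9	-3.4	186.21
Y	-1.3	-2.3	163.18
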