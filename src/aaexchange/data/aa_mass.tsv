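aa	mass_da
A	89.09
C	121.16
D	133.10
E	147.13
F	165.19
G	75.07
H	155.15
I	131.17
K	146.19
L	131.17
M	149.21
N	132.12
P	115.13
Q	146.15
R	174.20
S	105.09
T	119.12
V	117.15
W	204.23
Y	181.19
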