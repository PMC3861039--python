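aa	count
A	736050
C	241500
D	497700
E	745500
F	383250
G	690900
H	276150
I	454650
K	600600
L	1046850
M	223650
N	376950
P	662550
Q	500850
R	592200
S	874650
T	562800
V	625800
W	128100
Y	279300
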