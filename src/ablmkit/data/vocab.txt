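<cls>
<pad>
<eos>
<unk>
L
A
G
V
S
E
R
T
I
D
P
K
Q
N
F
Y
M
H
W
C
X
B
U
Z
O
.
-
<null_1>
<mask>
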