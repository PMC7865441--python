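code,value,approx
A,0.37,
C,0.25,
D,0.30,
E,0.42,
F,0.17,
G,0.13,
H,0.20,
I,0.39,
K,0.56,
L,0.24,
M,0.36,
N,0.27,
P,1.00,
Q,0.53,
R,0.38,
S,0.24,
T,0.32,
V,0.39,
W,0.25,
Y,0.25,
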