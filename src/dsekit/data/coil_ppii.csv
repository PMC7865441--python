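code,value,approx
A,0.48,
C,0.38,
D,0.34,
E,0.38,
F,0.36,
G,0.21,
H,0.28,
I,0.39,
K,0.35,
L,0.47,
M,0.38,
N,0.31,
P,0.81,
Q,0.35,
R,0.32,
S,0.31,
T,0.24,
V,0.34,
W,0.35,
Y,0.37,
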