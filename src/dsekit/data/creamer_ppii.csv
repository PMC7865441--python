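code,value,approx
A,0.61,
C,0.55,
D,0.63,
E,0.61,
F,0.58,
G,0.58,
H,0.55,
I,0.50,
K,0.59,
L,0.58,
M,0.55,
N,0.55,
P,0.67,
Q,0.66,
R,0.61,
S,0.58,
T,0.53,
V,0.49,
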