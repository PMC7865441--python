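code,value,approx
A,0.818,
C,0.557,
D,0.552,
E,0.684,
F,0.639,
H,0.428,
I,0.519,
K,0.581,
L,0.574,
M,0.498,
N,0.667,
Q,0.654,
R,0.638,
S,0.774,
T,0.553,
V,0.743,
W,0.764,
Y,0.630,
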