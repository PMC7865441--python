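code,value,approx
A,-0.258,
C,0.570,
D,0.635,
E,0.433,
F,0.672,
G,1.62,
H,0.525,
I,0.445,
K,0.108,
L,0.022,
M,0.251,
N,0.635,
P,4,
Q,0.314,
R,-0.047,
S,0.525,
T,1.07,
V,0.797,
W,0.6,approx
Y,0.4,approx
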