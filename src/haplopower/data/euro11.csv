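label,freq
H,0.41
I,0.02
J,0.11
K,0.08
M,0.01
T,0.13
U,0.15
V,0.13
W,0.02
X,0.02
other,0.02
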