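label,x,y
NEST,0.36,-0.2
F1,0.0,0.0
F2,0.18,0.0
F3,0.36,0.0
F4,0.54,0.0
F5,0.72,0.0
F6,0.6,0.2078
F7,0.48,0.4157
F8,0.36,0.6235
F9,0.24,0.4157
F10,0.12,0.2078
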