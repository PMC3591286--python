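label,x,y
NEST,-0.15,0.03
F1,0.0,0.0
F2,0.22,0.0
F3,0.44,0.0
F4,0.66,0.0
F5,0.88,0.0
F6,0.88,0.06
F7,0.66,0.06
F8,0.44,0.06
F9,0.22,0.06
F10,0.0,0.06
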