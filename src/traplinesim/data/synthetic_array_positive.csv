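label,x,y
NEST,0.55,-0.12
F1,0.45,0.0
F2,0.4229,0.1539
F3,0.3447,0.2893
F4,0.225,0.3897
F5,0.0781,0.4432
F6,-0.0781,0.4432
F7,-0.225,0.3897
F8,-0.3447,0.2893
F9,-0.4229,0.1539
F10,-0.45,0.0
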