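pair,globular,globular_state,rod,rod_state
G0F-GN,G0F-GN(3),p3,G0F-GN(6),p6
G1,G1(3),p3,G1(6),p3
G1F,G1F(3),p3,G1F(6),p6
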