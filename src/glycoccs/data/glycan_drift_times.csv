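species,mz,drift_ms
G0F-GN(3),669.8,5.31
G0F-GN(6),669.8,5.73
G0,698.3,6.07
G0F,771.3,6.76
G1(3),779.3,5.80
G1(6),779.3,6.69
G1F(3),852.3,6.62
G1F(6),852.3,6.97
G2,860.3,6.42
G2F,933.4,7.04
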