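species,mz,drift_ms,ccs_A2
PolyAla11,400.5,3.52,296
PolyAla12,436.0,3.79,309
PolyAla13,471.5,4.07,320
PolyAla14,507.0,4.35,333
PolyAla15,542.5,4.69,344
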