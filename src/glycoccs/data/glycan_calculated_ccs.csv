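glycan,exp_n2_A2,calc_n2_p3,calc_n2_p6,calc_he_p3,calc_he_p6
G0F-GN(3),371,400,,279,
G0F-GN(6),388,,427,,296
G0,402,425,420,298,292
G0F,431,464,447,328,315
G1(3),391,423,436,297,309
G1(6),428,444,450,313,318
G1F(3),425,454,476,322,338
G1F(6),440,475,467,340,336
G2,417,477,455,340,325
G2F,442,475,481,342,350
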