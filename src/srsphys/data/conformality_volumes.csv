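isodose_level_pct,volume_cm3
80,13.38
70,16.51
60,19.95
50,24.57
40,32.30
30,48.73
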