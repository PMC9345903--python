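gene	C0	C1	C2	C3	C4
G1	1.0	1.5	2.0	2.5	3.0
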