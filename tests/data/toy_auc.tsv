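ccl	cmpA	cmpB	cmpC
C0	0.7		1.0
C1	0.8		1.1
C2	0.9	2.0	1.2
C3	1.0	2.1	1.3
C4	1.1	2.2	1.4
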