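ccl	tissue
C0	kidney
C1	kidney
C2	kidney
C3	kidney
C4	haematopoietic_and_lymphoid_tissue
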