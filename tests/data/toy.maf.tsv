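Tumor_Sample_Barcode	Hugo_Symbol	Variant_Classification
S1	G00	Nonsense_Mutation
S1	G01	Nonsense_Mutation
S1	G02	Nonsense_Mutation
S1	G03	Nonsense_Mutation
S1	G04	Nonsense_Mutation
S1	G05	Nonsense_Mutation
S1	G06	Nonsense_Mutation
S1	G07	Nonsense_Mutation
S1	G08	Nonsense_Mutation
S1	G00	Frame_Shift_Del
S1	G90	Silent
S1	G91	Silent
S2	G00	Frame_Shift_Ins
S2	G01	Frame_Shift_Ins
S2	G02	Frame_Shift_Ins
S2	G03	Frame_Shift_Ins
S2	G04	Frame_Shift_Ins
S2	G05	Frame_Shift_Ins
S2	G06	Frame_Shift_Ins
S2	G07	Frame_Shift_Ins
S2	G08	Frame_Shift_Ins
S3	G20	Silent
S3	G21	Silent
S3	G22	Silent
S3	G23	Silent
S3	G24	Silent
S3	G25	Silent
S3	G26	Silent
S3	G27	Silent
S3	G28	Silent
S3	G29	Silent
S3	G50	Nonsense_Mutation
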