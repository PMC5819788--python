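species	chrom_label	genome	long_um	short_um	satellite	sites	ploidy	x
ANCESTRAL_B	B1	B	3.500000	2.900000	0	45S:LONG:INTERCALARY:0.550000	2	7
ANCESTRAL_B	B1	B	3.500000	2.900000	0	45S:LONG:INTERCALARY:0.550000	2	7
ANCESTRAL_B	B2	B	3.300000	2.800000	0	5S:LONG:INTERCALARY:0.500000	2	7
ANCESTRAL_B	B2	B	3.300000	2.800000	0	5S:LONG:INTERCALARY:0.500000	2	7
ANCESTRAL_B	B3	B	3.100000	2.600000	0	5S:LONG:SUBTELOMERIC:0.850000	2	7
ANCESTRAL_B	B3	B	3.100000	2.600000	0	5S:LONG:SUBTELOMERIC:0.850000	2	7
ANCESTRAL_B	B4	B	2.900000	2.400000	0		2	7
ANCESTRAL_B	B4	B	2.900000	2.400000	0		2	7
ANCESTRAL_B	B5	B	2.700000	2.200000	0		2	7
ANCESTRAL_B	B5	B	2.700000	2.200000	0		2	7
ANCESTRAL_B	B6	B	2.500000	2.000000	0		2	7
ANCESTRAL_B	B6	B	2.500000	2.000000	0		2	7
ANCESTRAL_B	B7	B	2.300000	1.800000	0		2	7
ANCESTRAL_B	B7	B	2.300000	1.800000	0		2	7
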