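species	chrom_label	genome	long_um	short_um	satellite	sites	ploidy	x
PROTO_A	A1	A	4.000000	4.000000	SHORT:0.800000	45S:SHORT:SUBTELOMERIC:0.850000	2	7
PROTO_A	A1	A	4.000000	4.000000	SHORT:0.800000	45S:SHORT:SUBTELOMERIC:0.850000	2	7
PROTO_A	A2	A	3.000000	3.000000	0	5S:LONG:SUBTELOMERIC:0.850000	2	7
PROTO_A	A2	A	3.000000	3.000000	0	5S:LONG:SUBTELOMERIC:0.850000	2	7
PROTO_A	A3	A	3.500000	3.500000	0		2	7
PROTO_A	A3	A	3.500000	3.500000	0		2	7
PROTO_A	A4	A	3.250000	3.250000	0		2	7
PROTO_A	A4	A	3.250000	3.250000	0		2	7
PROTO_A	A5	A	3.000000	3.000000	0		2	7
PROTO_A	A5	A	3.000000	3.000000	0		2	7
PROTO_A	A6	A	2.800000	2.800000	0		2	7
PROTO_A	A6	A	2.800000	2.800000	0		2	7
PROTO_A	A7	A	3.000000	3.000000	0	5S:LONG:CENTROMERIC_PROXIMAL:0.100000	2	7
PROTO_A	A7	A	3.000000	3.000000	0	5S:LONG:CENTROMERIC_PROXIMAL:0.100000	2	7
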