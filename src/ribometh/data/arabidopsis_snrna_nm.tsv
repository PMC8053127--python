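#rna_id	position	base	guides	noncanonical
U2	13	G	SnoR113	0
U2	20	G	SnoR127	0
U2	26	G		0
U2	29	C	SnoR101	0
U2	31	A	SnoR125;SnoR31	0
U2	39	A	SnoR24	0
U2	41	C	SnoR176	0
U4	67	A		0
U5	40	G	SnoR102	0
U5	44	U		0
U5	48	C	SnoR130	0
U6	27	U	SnoR167	0
U6	43	A	U27	0
U6	48	A	SnoR53Y	0
U6	57	C		0
U6	63	C	SnoR26	0
U6	65	A		0
U6	75	G	SnoR126	0
U6	84	G	SnoR126	0
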