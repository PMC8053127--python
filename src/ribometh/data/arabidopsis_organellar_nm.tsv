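#rna_id	position	base	guides	noncanonical
Pt_SSU	1351	C		0
Pt_SSU	1358	C		0
Pt_LSU	1935	C		0
Pt_LSU	2269	G		0
Pt_LSU	2571	G		0
Mt_SSU	1751	C		0
Mt_SSU	1758	C		0
Mt_LSU	2216	C		0
Mt_LSU	2538	G		0
Mt_LSU	2835	U		0
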