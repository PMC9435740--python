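sample_id	species	replicate	batch
H1	H	1	b1
H2	H	2	b2
H3	H	3	b3
C1	C	1	b1
C2	C	2	b2
C3	C	3	b3
G1	G	1	b1
G2	G	2	b2
G3	G	3	b3
O1	O	1	b1
O2	O	2	b2
O3	O	3	b3
M1	M	1	b1
M2	M	2	b2
M3	M	3	b3
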