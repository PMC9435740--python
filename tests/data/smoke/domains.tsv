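transcript_id	gene_id	domains
g0000t1	g0000	g0000:A,g0000:B
g0000t2	g0000	g0000:A
g0001t1	g0001	g0001:A,g0001:B
g0001t2	g0001	g0001:A
g0001tG	g0001	g0001:A
g0002t1	g0002	g0002:A,g0002:B
g0002t2	g0002	g0002:A
g0003t1	g0003	g0003:A,g0003:B
g0003t2	g0003	g0003:A
g0004t1	g0004	g0004:A,g0004:B
g0004t2	g0004	g0004:A
g0004tX	g0004	g0004:A
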