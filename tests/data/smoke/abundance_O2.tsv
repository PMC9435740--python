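target_id	est_counts	tpm
g0000t1	1888.0	132881.28283172206
g0000t2	1103.0	96002.17081797888
g0001t1	136.0	9015.447697047757
g0001t2	59.0	4771.003505926191
g0001tG	139.0	8475.201460404915
g0002t1	263.0	18173.921213175236
g0002t2	420.0	39252.40728271034
g0003t1	5471.0	319896.0960895288
g0003t2	3900.0	306671.51699693885
g0004t1	551.0	32892.36253251501
g0004t2	443.0	31968.589572051882
g0004tX	0.0	0.0
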