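target_id	est_counts	tpm
g0000t1	4055.0	257180.14191624062
g0000t2	1271.0	99686.38393998132
g0001t1	654.0	39067.074349413386
g0001t2	258.0	18800.18751306275
g0001tG	0.0	0.0
g0002t1	601.0	37424.16467099954
g0002t2	1460.0	122957.38344894833
g0003t1	3967.0	209020.64171872608
g0003t2	2304.0	163258.59706612182
g0004t1	498.0	26789.0654408101
g0004t2	397.0	25816.35993569604
g0004tX	0.0	0.0
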