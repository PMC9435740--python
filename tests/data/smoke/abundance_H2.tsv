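target_id	est_counts	tpm
g0000t1	3895.0	253380.5098626233
g0000t2	1306.0	105063.6875082655
g0001t1	723.0	44298.66196699647
g0001t2	335.0	25038.393048451948
g0001tG	0.0	0.0
g0002t1	1247.0	79645.87127146378
g0002t2	443.0	38267.0209196343
g0003t1	4200.0	226984.10047138526
g0003t2	2599.0	188894.3793750417
g0004t1	258.0	14235.315500767128
g0004t2	219.0	14607.227261347962
g0004tX	201.0	9584.832814022779
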