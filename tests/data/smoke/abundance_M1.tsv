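target_id	est_counts	tpm
g0000t1	1975.0	138271.78269852712
g0000t2	896.0	77574.35811095414
g0001t1	723.0	47675.068649831286
g0001t2	273.0	21959.629631475218
g0001tG	0.0	0.0
g0002t1	292.0	20071.52561187918
g0002t2	724.0	67306.99667626001
g0003t1	5470.0	318151.65860557696
g0003t2	2938.0	229808.0649709653
g0004t1	619.0	36756.88998725668
g0004t2	591.0	42424.025057274106
g0004tX	0.0	0.0
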