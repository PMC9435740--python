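target_id	est_counts	tpm
g0000t1	2294.0	134218.68744314887
g0000t2	1123.0	81253.68179779411
g0001t1	928.0	51139.22212509181
g0001t2	609.0	40938.57941396977
g0001tG	0.0	0.0
g0002t1	970.0	55721.44605113843
g0002t2	362.0	28124.40402767026
g0003t1	5545.0	269526.53464624815
g0003t2	4521.0	295529.6729721826
g0004t1	370.0	18361.279653597463
g0004t2	274.0	16437.208508234173
g0004tX	204.0	8749.283360924197
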