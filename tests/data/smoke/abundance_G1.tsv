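target_id	est_counts	tpm
g0000t1	1753.0	162029.53549661805
g0000t2	768.0	87784.37264949172
g0001t1	535.0	46574.9739366796
g0001t2	265.0	28141.94090321278
g0001tG	0.0	0.0
g0002t1	499.0	45283.9066897461
g0002t2	1290.0	158327.79557331806
g0003t1	3204.0	246028.36555779426
g0003t2	1748.0	180509.76943482234
g0004t1	294.0	23048.42473973689
g0004t2	235.0	22270.915018580257
g0004tX	0.0	0.0
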