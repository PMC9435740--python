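target_id	est_counts	tpm
g0000t1	2551.0	165196.52775583375
g0000t2	1211.0	96979.13767747111
g0001t1	643.0	39218.23067610098
g0001t2	319.0	23734.333528962296
g0001tG	0.0	0.0
g0002t1	907.0	57667.193160794166
g0002t2	329.0	28290.559588751526
g0003t1	5482.0	294923.84717006277
g0003t2	3051.0	220739.30764582893
g0004t1	470.0	25814.87112810536
g0004t2	397.0	26359.60453852471
g0004tX	444.0	21076.387129564326
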