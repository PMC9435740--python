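target_id	est_counts	tpm
g0000t1	3927.0	154361.40620634033
g0000t2	2425.0	117878.14334536744
g0001t1	602.0	22287.475762412774
g0001t2	245.0	11064.704279212012
g0001tG	0.0	0.0
g0002t1	286.0	11037.607044242513
g0002t2	721.0	37632.95087751665
g0003t1	8593.0	280609.93293247314
g0003t2	7830.0	343863.9117629399
g0004t1	338.0	11268.76111846749
g0004t2	248.0	9995.10667102779
g0004tX	0.0	0.0
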