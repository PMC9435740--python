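target_id	est_counts	tpm
g0000t1	1019.0	48169.82122031749
g0000t2	417.0	24377.02059883083
g0001t1	378.0	16829.810189237982
g0001t2	196.0	10645.175449352524
g0001tG	231.0	9459.89330898344
g0002t1	426.0	19771.586534966256
g0002t2	896.0	56242.42579330045
g0003t1	10223.0	401476.0239466522
g0003t2	6581.0	347567.9749520986
g0004t1	888.0	35603.7270985824
g0004t2	616.0	29856.540907677692
g0004tX	0.0	0.0
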