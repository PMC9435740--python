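target_id	est_counts	tpm
g0000t1	1988.0	105247.76028250292
g0000t2	805.0	52703.090368321406
g0001t1	785.0	39142.873739898394
g0001t2	357.0	21715.03834417239
g0001tG	0.0	0.0
g0002t1	225.0	11695.26511278956
g0002t2	461.0	32408.02698740757
g0003t1	9272.0	407802.8989345753
g0003t2	5039.0	298049.1264077299
g0004t1	310.0	13920.018860248658
g0004t2	319.0	17315.900962353826
g0004tX	0.0	0.0
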