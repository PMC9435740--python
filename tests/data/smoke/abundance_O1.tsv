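target_id	est_counts	tpm
g0000t1	1668.0	67698.81261075819
g0000t2	528.0	26501.023465840208
g0001t1	1065.0	40711.88214451965
g0001t2	477.0	22243.303424000067
g0001tG	470.0	16525.56326762054
g0002t1	357.0	14226.048719317596
g0002t2	899.0	48450.68046057712
g0003t1	9076.0	306027.106214564
g0003t2	9110.0	413095.4338344875
g0004t1	574.0	19759.61802405986
g0004t2	595.0	24760.52783425531
g0004tX	0.0	0.0
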