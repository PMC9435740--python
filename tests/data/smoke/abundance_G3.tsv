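target_id	est_counts	tpm
g0000t1	1356.0	155037.9232898369
g0000t2	518.0	73240.57269241568
g0001t1	623.0	67089.2392379694
g0001t2	252.0	33103.55959530692
g0001tG	0.0	0.0
g0002t1	519.0	58260.83183321225
g0002t2	856.0	129959.25152599413
g0003t1	2209.0	209823.61830668806
g0003t2	1572.0	200806.51864857608
g0004t1	469.0	45481.28672147534
g0004t2	232.0	27197.198148525214
g0004tX	0.0	0.0
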