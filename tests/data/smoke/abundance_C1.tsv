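target_id	est_counts	tpm
g0000t1	2334.0	129777.1403133448
g0000t2	689.0	47376.207171434944
g0001t1	1092.0	57188.21673041577
g0001t2	370.0	23637.142550097808
g0001tG	0.0	0.0
g0002t1	312.0	17032.681000227723
g0002t2	690.0	50945.00661716916
g0003t1	7713.0	356287.90781615407
g0003t2	4150.0	257805.66566989245
g0004t1	645.0	30418.564160444952
g0004t2	518.0	29531.467970818398
g0004tX	0.0	0.0
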