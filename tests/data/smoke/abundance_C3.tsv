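target_id	est_counts	tpm
g0000t1	2615.0	112672.21944154958
g0000t2	1180.0	62873.96981141279
g0001t1	1127.0	45735.73256330089
g0001t2	371.0	18366.016389015942
g0001tG	0.0	0.0
g0002t1	636.0	26905.02141144154
g0002t2	1157.0	66196.29746045014
g0003t1	9695.0	347035.07600667427
g0003t2	5888.0	283439.2366259345
g0004t1	524.0	19149.528723642823
g0004t2	399.0	17626.90156657764
g0004tX	0.0	0.0
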