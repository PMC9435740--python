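target_id	est_counts	tpm
g0000t1	2059.0	119857.41944167417
g0000t2	648.0	46647.38483184673
g0001t1	628.0	34431.40840642376
g0001t2	335.0	22405.223747325035
g0001tG	0.0	0.0
g0002t1	214.0	12230.759318892548
g0002t2	611.0	47228.58896637629
g0003t1	8138.0	393556.1152798789
g0003t2	4134.0	268859.91746728314
g0004t1	649.0	32043.12916924227
g0004t2	381.0	22740.05337105702
g0004tX	0.0	0.0
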