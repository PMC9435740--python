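chr0000	primatesplice	exon	151	297	.	+	.	gene_id "g0000"; transcript_id "g0000t1";
chr0000	primatesplice	exon	435	557	.	+	.	gene_id "g0000"; transcript_id "g0000t1";
chr0000	primatesplice	exon	776	868	.	+	.	gene_id "g0000"; transcript_id "g0000t1";
chr0000	primatesplice	exon	1113	1235	.	+	.	gene_id "g0000"; transcript_id "g0000t1";
chr0000	primatesplice	exon	151	297	.	+	.	gene_id "g0000"; transcript_id "g0000t2";
chr0000	primatesplice	exon	435	557	.	+	.	gene_id "g0000"; transcript_id "g0000t2";
chr0000	primatesplice	exon	1113	1235	.	+	.	gene_id "g0000"; transcript_id "g0000t2";
chr0001	primatesplice	exon	151	267	.	+	.	gene_id "g0001"; transcript_id "g0001t1";
chr0001	primatesplice	exon	473	565	.	+	.	gene_id "g0001"; transcript_id "g0001t1";
chr0001	primatesplice	exon	826	933	.	+	.	gene_id "g0001"; transcript_id "g0001t1";
chr0001	primatesplice	exon	1132	1224	.	+	.	gene_id "g0001"; transcript_id "g0001t1";
chr0001	primatesplice	exon	1377	1481	.	+	.	gene_id "g0001"; transcript_id "g0001t1";
chr0001	primatesplice	exon	151	267	.	+	.	gene_id "g0001"; transcript_id "g0001t2";
chr0001	primatesplice	exon	826	933	.	+	.	gene_id "g0001"; transcript_id "g0001t2";
chr0001	primatesplice	exon	1132	1224	.	+	.	gene_id "g0001"; transcript_id "g0001t2";
chr0001	primatesplice	exon	1377	1481	.	+	.	gene_id "g0001"; transcript_id "g0001t2";
chr0001	primatesplice	exon	151	267	.	+	.	gene_id "g0001"; transcript_id "g0001tG";
chr0001	primatesplice	exon	473	610	.	+	.	gene_id "g0001"; transcript_id "g0001tG";
chr0001	primatesplice	exon	826	933	.	+	.	gene_id "g0001"; transcript_id "g0001tG";
chr0001	primatesplice	exon	1132	1224	.	+	.	gene_id "g0001"; transcript_id "g0001tG";
chr0001	primatesplice	exon	1377	1481	.	+	.	gene_id "g0001"; transcript_id "g0001tG";
chr0002	primatesplice	exon	151	288	.	+	.	gene_id "g0002"; transcript_id "g0002t1";
chr0002	primatesplice	exon	508	600	.	+	.	gene_id "g0002"; transcript_id "g0002t1";
chr0002	primatesplice	exon	836	964	.	+	.	gene_id "g0002"; transcript_id "g0002t1";
chr0002	primatesplice	exon	1149	1283	.	+	.	gene_id "g0002"; transcript_id "g0002t1";
chr0002	primatesplice	exon	151	288	.	+	.	gene_id "g0002"; transcript_id "g0002t2";
chr0002	primatesplice	exon	508	600	.	+	.	gene_id "g0002"; transcript_id "g0002t2";
chr0002	primatesplice	exon	1149	1283	.	+	.	gene_id "g0002"; transcript_id "g0002t2";
chr0003	primatesplice	exon	151	294	.	+	.	gene_id "g0003"; transcript_id "g0003t1";
chr0003	primatesplice	exon	490	636	.	+	.	gene_id "g0003"; transcript_id "g0003t1";
chr0003	primatesplice	exon	796	945	.	+	.	gene_id "g0003"; transcript_id "g0003t1";
chr0003	primatesplice	exon	1074	1217	.	+	.	gene_id "g0003"; transcript_id "g0003t1";
chr0003	primatesplice	exon	151	294	.	+	.	gene_id "g0003"; transcript_id "g0003t2";
chr0003	primatesplice	exon	490	636	.	+	.	gene_id "g0003"; transcript_id "g0003t2";
chr0003	primatesplice	exon	1074	1217	.	+	.	gene_id "g0003"; transcript_id "g0003t2";
chr0004	primatesplice	exon	151	246	.	+	.	gene_id "g0004"; transcript_id "g0004t1";
chr0004	primatesplice	exon	404	529	.	+	.	gene_id "g0004"; transcript_id "g0004t1";
chr0004	primatesplice	exon	790	888	.	+	.	gene_id "g0004"; transcript_id "g0004t1";
chr0004	primatesplice	exon	1087	1227	.	+	.	gene_id "g0004"; transcript_id "g0004t1";
chr0004	primatesplice	exon	1350	1460	.	+	.	gene_id "g0004"; transcript_id "g0004t1";
chr0004	primatesplice	exon	151	246	.	+	.	gene_id "g0004"; transcript_id "g0004t2";
chr0004	primatesplice	exon	404	529	.	+	.	gene_id "g0004"; transcript_id "g0004t2";
chr0004	primatesplice	exon	1087	1227	.	+	.	gene_id "g0004"; transcript_id "g0004t2";
chr0004	primatesplice	exon	1350	1460	.	+	.	gene_id "g0004"; transcript_id "g0004t2";
chr0004	primatesplice	exon	151	246	.	+	.	gene_id "g0004"; transcript_id "g0004tX";
chr0004	primatesplice	exon	404	529	.	+	.	gene_id "g0004"; transcript_id "g0004tX";
chr0004	primatesplice	exon	590	679	.	+	.	gene_id "g0004"; transcript_id "g0004tX";
chr0004	primatesplice	exon	790	888	.	+	.	gene_id "g0004"; transcript_id "g0004tX";
chr0004	primatesplice	exon	1087	1227	.	+	.	gene_id "g0004"; transcript_id "g0004tX";
chr0004	primatesplice	exon	1350	1460	.	+	.	gene_id "g0004"; transcript_id "g0004tX";
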