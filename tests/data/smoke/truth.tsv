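event_class	gene_id	feature_id	focal_species	effect	mechanism
canonicity_change	g0001	g0001:J610-825	O		donor
diu	g0002	g0002t1	H	0.4	usage_shift
novel_peptide_gene	g0003	g0003			unannotated_gene
species_specific_exon	g0004	g0004:ssx	H		exonization
species_specific_transcript	g0001	g0001tG	O	0.3	canonicity
species_specific_transcript	g0004	g0004tX	H	0.3	exonization
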