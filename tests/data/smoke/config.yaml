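alu_fraction: 0.8
batch_effect_sd: 0.0
deu_high_usage: 0.85
deu_low_usage: 0.15
diu_base_usage: 0.3
diu_delta: 0.4
exon_count_range:
- 4
- 5
exon_length_range:
- 90
- 150
flank: 150
gain_usage: 0.3
gene_mean_log2: 11.0
gene_sd_log2: 1.0
intron_length_range:
- 120
- 250
n_deu: 0
n_diu: 1
n_gain: 1
n_gain_canonicity: 1
n_genes: 5
n_novel_peptide: 1
n_rank_switch: 0
n_replicates: 3
n_ss_exon: 1
nb_dispersion: 0.1
rank_major_usage: 0.75
seed: 11
substitution_rate: 0.003
usage_jitter_sd: 0.15
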