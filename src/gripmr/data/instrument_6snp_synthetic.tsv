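## Synthetic 6-SNP weighted-score instrument for circulating 25(OH)D.
## Weights are per-allele effects on ln 25(OH)D, on the scale of published
## vitamin-D GWAS hits; ids/frequencies are synthetic stand-ins, not the
## genotyped variants of any cohort.
snp_id	effect_allele	weight	allele_freq
rs_syn_gc	T	0.089	0.28
rs_syn_dhcr7	T	0.036	0.75
rs_syn_cyp2r1	A	0.031	0.40
rs_syn_cyp24a1	T	0.026	0.79
rs_syn_amdhd1	T	0.017	0.40
rs_syn_sec23a	G	0.017	0.18
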