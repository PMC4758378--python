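# End-to-end synthetic run: simulate -> enrichment -> consensus -> promoter
# scan -> CAG correlation -> network prioritization. All stages derive their
# seeds from [run] seed; re-running reproduces every output byte for byte.

[run]
outdir = "uprhd_demo_run"
seed = 11

[expression]
n_genes = 400
n_case = 8
n_control = 8
planted_set_size = 40
effect = 1.5
noise_sd = 1.0
n_murine = 6
human_comparison = "human_ipsc"

[gsea]
metric = "signal2noise"
n_perm = 300
n_decoy_sets = 5

[consensus]
min_support = 4

[promoters]
upre_rate = 0.03
erse1_rate = 0.01
erse2_rate = 0.01
boosted_upre_rate = 0.8

[cag]
replicates = 4
effect = 2.0
noise_sd = 0.5
n_perm = 300
fdr = 0.01

[network]
n_nodes = 300
n_edges = 900
apoptosis_overlap = 40
htt_overlap = 6
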