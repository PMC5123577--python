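# Full-pipeline configuration for `biome-bridge run --config config.example.yaml`.
# Defaults reproduce the standard procedure: 1 per-mille main-OTU filter,
# 1% network filter, rho > 0.6 at one-sided P < 0.001, generalists at
# >= 16 of 21 habitats. Replace `synthetic` with otu_tables/metadata/taxonomy
# paths to analyse real data.
out_dir: results/run
seed: 1
synthetic:
  n_habitats: 21
  n_replicates: 3
  reads_per_sample: 5000
main_otu_threshold: 0.001
network_threshold: 0.01
rho_min: 0.6
alpha: 0.001
generalist_min: 16
qc_alpha: 0.001
min_count: 1
weight_domains: true
two_sided: false
bh_correct: false
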