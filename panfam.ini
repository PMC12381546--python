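; Example configuration for the worked example in README.md.
; CLI flags (--seed, --out) override these values.

[simulate]
n_genotypes = 6
n_families = 5
genome_length = 120000
substitution_rate = 0.01
duplicate_divergence = 0.02

[search]
k_seed = 15
identity = 0.90
coverage = 0.80
max_gap = 2000

[domains]
pssm_pseudocount = 1.0
pssm_instances = 30
calibration_windows = 10000

[pca]
kmer = 3
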