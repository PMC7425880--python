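# Demo pipeline configuration: a small synthetic cohort that runs end-to-end
# in a few minutes on one CPU.
out_dir: stiffpipe_demo
seed: 1
n_samples: 2000
n_variants: 2000
permutations: 200
genome_wide_p: 5.0e-8
suggestive_p: 1.0e-6
nominal_p: 0.05
bonferroni_divisor: 3
prune_r2: 0.5
instrument_ld_r2: 0.1
locus_window: 500000
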