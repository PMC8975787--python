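# Demo: full synthetic run (~20 s on one CPU).
outdir: demo_run
simulate: true
design:
  n_loci: 2000
  seed: 42
mcmc_iterations: 6000
mcmc_burn_in: 3000
mcmc_seed: 7
fst_threshold: 0.65
hybrid_cutoff: 0.20
random_intercept: year
delta_cutoff: 4.0
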