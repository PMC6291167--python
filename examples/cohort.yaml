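# Small synthetic cohort for a quick end-to-end run (~3 minutes).
cohort:
  n_subjects: 8
  group_mu: [0.3, 0.3, -0.8]
  group_delta: [1.0, 1.0, 0.8]
model:
  sampler:
    n_chains: 2
    n_warmup: 400
    n_draws: 400
stats:
  n_perm: 1000
  n_boot: 10000
seeds:
  simulate: 42
  fit: 1
  preprocess: 2
  deconvolve: 3
  stats: 4
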