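# pupilrl

Value-based decision pupillometry in Python: simulate a probabilistic
selection task and softmax Q-learning agents, fit a hierarchical Bayesian
two-learning-rate Q-learning model to choices, preprocess pupil time series,
deconvolve event-related pupil responses with single-trial value and
prediction-error covariates via cross-validated ridge regression, and run
group-level statistics. The whole pipeline is exercisable end to end on
synthetic data with known ground truth.

## Modules

| Module | What it does |
| --- | --- |
| `pupilrl.task` | Task schedules (3 learning pairs at 80/70/60 % reward, 15-pair transfer phase), probabilistic feedback, agent simulation |
| `pupilrl.qlearning` | Value updates with separate gain/loss learning rates, numerically stable softmax, choice likelihood, single-trial covariate trajectories |
| `pupilrl.hierfit` | Hierarchical Bayesian fit (probit-transformed subject parameters under group normals) via adaptive Metropolis-within-Gibbs, Rhat diagnostics, posterior modes, posterior-predictive simulation, AIC/BIC model comparison |
| `pupilrl.preproc` | Blink interpolation, residual-blink detection, zero-phase 0.05–4 Hz band-pass, per-run z-scoring, 20 Hz resampling, blink/saccade nuisance GLM, trial rejection |
| `pupilrl.deconv` | Sparse FIR design matrices (transients, normalized boxcar, covariates), ridge regression with cross-validated penalty over contiguous splits |
| `pupilrl.stats` | Cluster-based permutation tests (sign-flip null, maximal cluster size), interval summaries, bootstrap across-subject GLMs, feedback-response amplitude |
| `pupilrl.synth` | LTI synthetic pupil recordings with planted covariate modulations, 1/f noise, blink artifacts — ground truth for recovery tests |
| `pupilrl.pipeline` / `pupilrl.cli` / `pupilrl.io` / `pupilrl.config` | Stage runner with manifests, strict YAML config, tab-separated interchange formats, CLI |

## CLI

```bash
# full synthetic-cohort pipeline into a run directory
pupilrl full --config examples/cohort.yaml --out runs/demo

# or stage by stage (later stages check for upstream artifacts)
pupilrl simulate   --out runs/demo
pupilrl fit        --out runs/demo
pupilrl preprocess --out runs/demo
pupilrl deconvolve --out runs/demo
pupilrl stats      --out runs/demo
```

Flags: `--config` (YAML/JSON, strict keys — unknown keys are rejected with a
field-level message), `--seed-override`, `--log-level`. Every stage writes
tab-separated outputs plus a JSON manifest (config hash, seeds, version,
input checksums); identical configs reproduce identical outputs.

A minimal config (everything else defaults):

```yaml
cohort:
  n_subjects: 8
model:
  sampler: {n_chains: 2, n_warmup: 400, n_draws: 400}
stats:
  n_perm: 1000
  n_boot: 10000
```

## Data formats

All interchange formats are plain tab-separated text (see `pupilrl.io`):
trial tables (`phase, run, trial, pair, choice, outcome, rt, t_*`), pupil
traces (`time_s, diameter, run`), artifact annotations
(`event_type ∈ {blink_start, blink_end, saccade}, time_s, amplitude_deg`),
deconvolved betas (`regressor, lag_s, beta`), posterior draws in long format,
and cluster/bootstrap result tables. Proprietary eye-tracker files are out of
scope; convert them to these columns first.
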