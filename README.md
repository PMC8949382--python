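# actitraj

Accelerometer time-use trajectory profiling: turn minute-epoch count streams
into valid-day summaries, build compositional time-use features, identify
latent activity-trajectory profiles with a latent class linear mixed model,
and model profile membership from baseline covariates. Ships a seeded
synthetic-cohort generator with known two-class structure so every stage can
be exercised and verified against ground truth.

## What it does

* **`actitraj.cohort`** — synthetic cohorts: per-class, per-wave daily
  targets for sedentary (SB), light (LIPA) and moderate-to-vigorous (MVPA)
  minutes drive a semi-Markov minute-state process; counts are drawn inside
  disjoint cut-point ranges, days carry nocturnal and optional daytime
  non-wear blocks, and baseline covariates are class-linked. Presets:
  `high_separation_preset` (one class increasing MVPA over 24 months, one
  flat) and `zero_separation_preset` (identical classes).
* **`actitraj.processing`** — non-wear detection (>= 90 min of zero counts
  with <= 2-min interruption allowance), Freedson-era intensity cut-points
  (SB < 100, LIPA 100–1951, MVPA >= 1952 counts/min), strict-run bout
  detection (MVPA >= 10 min, SB >= 30 min), day summaries, the >= 3 valid
  days x >= 10 h wear validity filter, and the 150 min/week MVPA guideline.
* **`actitraj.features`** — fifteen features per participant-wave (means and
  between-day SDs per intensity, bout minutes/counts, counts, steps, and
  the three isometric log-ratio pivot coordinates), pooled z-scoring, and
  Spearman-based collinearity pruning (greedy, or the preset five-feature
  reproduction list).
* **`actitraj.lclmm`** — finite mixture of linear mixed models for
  multivariate longitudinal outcomes, fitted by multistart EM (k-means plus
  random starts), with posteriors, modal assignments, relative entropy,
  AIC/BIC, and canonical class ordering.
* **`actitraj.selection`** — fit G = 1..5, tabulate fit indices, and select
  the class count (highest lowest-mean-posterior, then entropy, with a
  minimum-class-share floor; AIC/BIC reported but not dispositive).
* **`actitraj.predictors`** — logistic regression with forced core terms
  (gender, age, randomisation), backward elimination of candidates by
  AIC/BIC, odds ratios with Wald intervals, and diagnostics (logit
  linearity, VIF, Cook's distance).
* **`actitraj.pipeline` / CLI** — config-driven end-to-end runner emitting
  a fit-index table, baseline-characteristics-by-profile table, predictor
  table, and per-profile mean z trajectories with 95% CIs.

## CLI

The pipeline is driven by a single YAML config (see
`examples/demo_config.yaml`):

```bash
actitraj run-all -c examples/demo_config.yaml
# or stage by stage:
actitraj simulate -c examples/demo_config.yaml
actitraj process  -c examples/demo_config.yaml
actitraj features -c examples/demo_config.yaml
actitraj fit      -c examples/demo_config.yaml
actitraj predict  -c examples/demo_config.yaml
```

Outputs (CSV/JSON) land in the configured `outdir`: `fit_table.csv`,
`selection.json`, `characteristics.csv`, `predictors.csv`,
`trajectories.csv`, plus intermediate epoch/day/feature tables and a run
log. Reruns with the same config and seed are byte-identical.

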