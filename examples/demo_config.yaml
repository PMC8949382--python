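# Demo: synthetic two-class cohort through the whole pipeline.
seed: 7
outdir: scratch/demo
synthetic:
  preset: high_separation
  n_participants: 60
pruning:
  policy: preset
  threshold: 0.9
lclmm:
  G_list: [1, 2, 3]
  n_starts: 2
  max_iter: 800
predictors:
  criterion: aic
  candidates: [bmi, hypertension, copd, other_disease, guideline]
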