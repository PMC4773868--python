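# periyield

Two-stage prediction of soluble periplasmic protein expression in
*E. coli* from the amino-acid sequence of a signal-peptide + target-protein
fusion.

Stage 1 classifies the sequence into a **high** (≥100 mg/l), **medium**
(0.5–100 mg/l) or **low** (≤0.5 mg/l) soluble-expression class with an
RBF-kernel support-vector classifier (one-against-one multi-class with
pairwise-coupled class probabilities). Stage 2 routes the sequence to the
epsilon-SVR regressor of the assigned class, which outputs the real-valued
yield in mg/l, clamped to the class interval.

The package contains the full training machinery, so models can be
retrained from any labelled dataset:

- **`sequence_features`** — the 7,903-feature scheme: 122 base features
  (length, residue and group compositions, maximum consecutive runs,
  charge, pI, and 11 predicted properties behind a pluggable
  deterministic predictor suite), all 7,381 pairwise product features, and
  400 overlapping dipeptide occurrence counts; plus the curated per-task
  feature subsets.
- **`preprocessing`** — Z-score standardization (sample SD) fitted on
  training data and frozen into the model.
- **`feature_selection`** — correlation-based feature selection (CFS
  merit) with greedy subset-size forward search.
- **`two_stage_model`** — grid-searched SVC + three class-specific SVRs,
  training, prediction, persistence-ready model objects.
- **`evaluation`** — macro-averaged multi-class metrics, PCC/MAE/RMSE,
  repeated stratified 10×10-fold CV, LOOCV, leave-one-feature-out
  ablation.
- **`io_cli`** — FASTA and TSV I/O, stratified 85:15 splitting, versioned
  model bundles, YAML run configuration.
- **`synthetic_data`** — planted-signal dataset generator so selection,
  training and evaluation are testable end to end offline.

## CLI

```sh
# generate a synthetic labelled dataset (TSV: id, sequence, yield_mg_per_l)
periyield --seed 1 simulate -o train.tsv --n 98 --planted dp_QD:1.0 --boost 4

# extract the full 7,903-feature table from FASTA
periyield extract sequences.fasta -o features.tsv

# train (CFS selection by default; --preset-features uses the curated subsets)
periyield --seed 1 train train.tsv -o model.joblib

# predict: id, class, P(High), P(Low), P(Medium), yield_mg_per_l
periyield predict model.joblib sequences.fasta -o predictions.tsv

# repeated 10x10-fold CV or LOOCV report
periyield evaluate train.tsv -o report.tsv --method cv

# leave-one-feature-out ablation of the classification subset
periyield ablate train.tsv -o ablation.tsv
```

A YAML file passed via `--config` can override registry residue groups,
hyperparameter grids (`model.svc_grid`, `model.svr_grid`), the yield cap,
and the regression target scale (`model.log_targets`).

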