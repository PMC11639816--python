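# oxytriage

A hypoxemia-severity triage pipeline for ICU vital-sign time series:

* **scoring** — NEWS2+ TAG scores per vital (age-stratified band tables) and
  SpO₂-based 4-class hypoxemia severity labels (adult with/without COPD,
  pediatric).  Threshold tables ship as an editable YAML config; printed
  overlaps/gaps are canonicalized alarm-favorably at load time and every edit
  is logged in a machine-readable corrections report.
* **preprocess** — duplicate merging, plausibility clamping, chained-equation
  imputation with boosted-tree regressors, linear interpolation onto a
  1-minute grid, BMI/MAP derivation, and per-cell provenance masks
  (0 observed / 1 synthetic).  Output is the 41-column model matrix
  (12 numeric + 7 one-hot race + 6 TAG + 16 mask features).
* **datasets** — −5-minute shift-lag labels, 5-minute sliding windows
  (stride 1), 1024-row padded segments (pad value 1000), patient-wise
  75/12.5/12.5 splits, inverse-frequency class weights.
* **models** — a declarative tree harness (three boosted rows + random
  forest, engines pluggable behind a registry; scikit-learn histogram
  gradient boosting backs the boosted rows here), a compact TPE
  hyperparameter search with 1−AUC and log-loss objectives, soft/hard voting
  ensembles, and masked LSTM/GRU classifiers written in NumPy with
  hand-derived BPTT (gradient-checked), closed-form parameter accounting,
  and padding-invariant inference.
* **evaluate** — confusion matrices, per-class/macro/weighted metrics,
  generalized multi-class MCC, one-vs-rest AUROC/AUPRC, gain-based feature
  importance reports, the SpO₂+heart-rate ablation experiment, and light EDA
  (Pearson correlations, standardized PCA).
* **synthetic** — an ICU-like cohort generator (episode-based SpO₂ dynamics,
  mean-reverting vitals, configurable demographics/admission-length/
  missingness laws) plus a planted-signal mode in which the label 5 minutes
  ahead is an exact function of (SpO₂, HR) now, enabling model-recovery and
  ablation experiments without restricted data.

## CLI

```sh
oxytriage simulate  --out cohort/ --seed 0 --n-patients 50
oxytriage preprocess --obs cohort/observations.csv --demo cohort/demographics.csv \
                     --out minutes.csv --seed 0
oxytriage score     --vitals vitals.csv --out scored.csv
oxytriage window    --data minutes.csv --out splits/ --lag 5
oxytriage train     --data splits/ --engine xgboost --out model_card.json
oxytriage evaluate  --data minutes.csv --out eda.json
```

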