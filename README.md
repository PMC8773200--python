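# il10pep

Descriptor-based machine-learning classification of **IL-10-inducing
immunosuppressive peptides**.

Interleukin-10 (IL-10) is a potent anti-inflammatory cytokine; short
MHC-II-binding peptides that trigger its release are candidate
immunotherapeutics for autoimmune and inflammatory disease. Screening such
epitopes experimentally is slow, so sequence-based classifiers are used to
triage candidates. `il10pep` is a reusable toolkit for building and
auditing such classifiers: it computes six families of amino-acid
descriptors, balances classes with a re-implemented SMOTE, selects
features by permutation importance, trains tree-ensemble models under
stratified cross-validation, and runs the class-comparison sequence
statistics (average composition, two-sample-logo position enrichment) that
accompany this kind of study. Everything is exercisable on synthetic data
shaped like the curated IL-10 benchmark (394 inducing / 848 non-inducing
MHC-II binders, mean length 16), so no downloads are required.

It is aimed at computational immunologists and ML-for-biology researchers
who want the full pipeline — including its known pitfalls, such as
oversampling before the train/test split — as tested, inspectable code.

## The model

For a peptide of length `N` over the 20-letter alphabet the feature
families are:

- **AAC** — residue frequencies `f(i) = N(i)/N` (20 features);
- **DPC** — ordered dipeptide frequencies `D(rs) = N_rs/(N−1)` (400);
- **CTD** — composition, transition and distribution of 3-group
  physicochemical partitions of the alphabet, 7 attributes × 21 values
  (147);
- **SOC** — sequence-order-coupling numbers
  `τ_d = Σ_i d(s_i, s_{i+d})²` over a 20×20 residue distance matrix,
  lags `d = 1..nlag`;
- **QSO** — quasi-sequence-order `X_r = f_r / S` and
  `X_d = w·τ_d / S` with the shared denominator
  `S = Σ_r f_r + w·Σ_d τ_d` (`w = 0.1`), so the vector sums to 1;
- **AutoC** — Moreau-Broto, Moran and Geary autocorrelation of eight
  z-scored per-residue property scales, lags 1–4.

The minority class is oversampled with SMOTE (synthetic points
`x + u·(x_nn − x)`, `u ∈ (0,1)` open), features are ranked by
permutation importance (mean accuracy drop) and kept up to a cumulative
importance threshold, and an extremely-randomized-trees classifier
(200 trees, depth 6, gini, balanced-subsample weights) — or LightGBM /
XGBoost — is evaluated by stratified 5-fold CV plus a single 20% holdout.
Metrics are accuracy, precision, recall, specificity, MCC, ROC AUC and
average precision.

## Worked example

```python
from il10pep import (SyntheticSpec, generate_synthetic, PeptideClassifier,
                     PipelineConfig, SmoteConfig)

data = generate_synthetic(SyntheticSpec(n_pos=394, n_neg=848,
                                        bias_strength=1.0, seed=7))
config = PipelineConfig(smote=SmoteConfig(percent=100, seed=7),
                        smote_order="train_only",
                        selection_threshold=None, seed=7)
results = PeptideClassifier(data, config).fit()
print(results.summary())
```

```
IL-10-inducing peptide classifier
=================================================
classifier        : extra_trees
smote             : 100% (train_only)
selection         : off
features          : 735 total, 735 kept
rows              : 993 train, 249 holdout
-------------------------------------------------
metric                CV mean +/- SD     holdout
Acc. %                  70.3 +/- 1.9      70.3
AUC                    0.726 +/- 0.029     0.720
Recall/Sen. %           52.1 +/- 3.8      49.4
Specificity %           78.8 +/- 1.3      80.0
Precision %             53.2 +/- 3.0      53.4
MCC                    0.310 +/- 0.046     0.300
AP (PR)                0.553 +/- 0.018     0.585
```

The synthetic positives are mildly enriched in R, H, I, L, M, F and Y and
the negatives in A, V, W and K (`bias_strength=1`), so a moderate holdout
AUC of 0.72 is the honest, leakage-free (`train_only`) signal at this
bias level; raising `bias_strength` to 3 pushes holdout AUC above 0.9,
and switching `smote_order` to `"before_split"` reproduces the published —
leaky — protocol, whose optimism the pipeline's fold audit makes visible.
Prediction then works from raw sequences:

```python
results.predict(["HRILMFYRGSTKLIVE", "AAVWKAGSTPLQNEAV"])
#        id  probability  label
# 0  query1     0.730251      1
# 1  query2     0.120681      0
```

The same workflow is available from the shell:

```bash
il10pep generate --pos 394 --neg 848 --bias 1 --seed 7 --out-dir data/
il10pep train --pos data/positives.fasta --neg data/negatives.fasta \
        --model-out model.joblib --report-out report.txt
il10pep predict data/positives.fasta --model model.joblib --out pred.csv
il10pep stats --pos data/positives.fasta --neg data/negatives.fasta \
        --out-dir stats/
```

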