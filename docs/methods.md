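# Methods

This note records the modelling assumptions, numerical conventions and
design decisions behind `il10pep`, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem and data model

The task is binary classification of short MHC-II-binding peptides
(9–30 residues, strict 20-letter alphabet) into IL-10-inducing (label 1)
and non-inducing (label 0). Real benchmark data for this task is an
external resource; the package therefore ships a synthetic generator whose
defaults emulate the benchmark's *structure*: 394 positives vs 848
negatives, lengths drawn from a shifted binomial
`L = L_min + Binomial(L_max − L_min, p)` with `p` chosen so the mean is 16
(defaults `L_min = 9`, `L_max = 30`; only the mean of the real data is
documented, so the range is an emulation, not a reconstruction).

Residues are drawn i.i.d. from a SwissProt-like background distribution.
Class signal is planted as a composition bias: the positive class
multiplies the background weight of {R, H, I, L, M, F, Y} by
`1 + 0.5·bias_strength`, the negative class does the same for
{A, V, W, K}, and each distribution is renormalised. These residue sets
mirror the class-dominant residues reported for the real benchmark. At
`bias_strength = 0` the classes are a single distribution (verified by a
chi-square null test); the default `bias_strength = 1` gives a moderate,
learnable signal.

What the generator deliberately does **not** emulate: positional motifs,
residue autocorrelation along the chain, peptide redundancy/homology
clusters, and label noise. Passing tests on synthetic data therefore
demonstrate that the machinery recovers planted compositional signal and
is calibrated under the null — not that any particular accuracy is
attainable on real epitope data.

## Descriptor conventions

All families index residues in fixed alphabetical order
(A, C, D, …, Y); dipeptides are row-major with the first residue outer.
Column names are family-prefixed and deterministic, so a feature matrix
is a pure function of (dataset, configuration).

- **CTD**: seven 3-group partitions (hydrophobicity, normalized van der
  Waals volume, polarity, polarizability, charge, secondary structure,
  solvent accessibility) in their standard descriptor-platform form.
  Transitions are unordered adjacent pairs divided by `N−1`. The
  distribution block reports, per group, the 1-based position of the 1st,
  `⌈p·n_g/100⌉`-th (p = 25, 50, 75) and last occurrence as `100·pos/N`;
  an empty group contributes five zeros.
- **SOC/QSO**: `τ_d = Σ (d_{i,i+d})²`; the QSO vector shares one
  denominator between the 20 composition terms and the `maxlag` coupling
  terms and so sums to 1. Type-1 components occupy indices 1–20 and
  type-2 components 21–20+maxlag (the standard indexing; printed variants
  that extend type-1 to `20+maxlag` are inconsistent with the shared
  denominator and are not used).
- **Autocorrelation**: property values are z-scored over the 20-letter
  alphabet before use (population SD), which makes Moreau-Broto
  scale-free; Moreau-Broto uses the averaged form divided by `N−l`.
  Moran normalises by the `1/N` sequence variance, Geary by the `1/(N−1)`
  sample variance. Sequences with zero property variance return 0 for
  Moran and Geary by convention.
- **Lags**: defaults `autoc_maxlag = 4` (the conventional printed lag
  range) and `qso_maxlag = soc_nlag = 8`, chosen so the defaults are valid
  at the benchmark's minimum length of 9 (`lag ≤ N−1`). A `wide()` preset
  raises all lags to 30 for long peptides. Encoding *fails loudly* when a
  lag reaches any sequence's length — silent truncation would make
  feature columns mean different things for different peptides.

### Vendored constants

- **Grantham distance matrix**: computed from the published
  composition/polarity/volume formula (α = 1.833, β = 0.1018,
  γ = 0.000399) and scaled so the mean off-diagonal distance is 100;
  this reproduces the published integer table to about ±1.
- **`pseaac3` distance matrix**: root-mean-square difference of
  standardized hydrophobicity, hydrophilicity (Hopp–Woods) and side-chain
  mass — the correlation construction of Chou's pseudo-amino-acid
  composition. It was chosen as the second matrix because it is exactly
  reconstructible from primary published scales; the Schneider–Wrede
  matrix often used in this role is only available as an opaque numeric
  table.
- **Autocorrelation properties**: eight canonical scales
  (Kyte–Doolittle hydrophobicity, Bhaskaran–Ponnuswamy flexibility,
  Charton–Charton polarizability and free energy of solution in water,
  Chothia accessible surface area, Bigelow residue volume, Charton steric
  parameter, Dayhoff relative mutability), shipped as a plain-text table
  with citations. Because every scale is z-scored before use, the
  descriptors are invariant to affine differences between editions of
  these scales.

## SMOTE

Re-implemented from the definition: for each minority row,
`percent/100` synthetic rows are formed as `x + u·(x_nn − x)` with a
neighbour drawn uniformly from the k nearest minority rows (Euclidean,
self excluded, ties broken by row index) and `u` uniform on the *open*
interval (0, 1), enforced by rejection. The literal reading of
`k = percent/100` gives k = 1 at 100% oversampling; that is the default
("percent" mode) for replication, with the classic k = 5 available and
recommended otherwise. Neighbour search runs on a min-max [0,1] copy of
the features (fitted on the data passed in) while interpolation happens in
the original space — equivalent for per-feature affine scalings, and it
keeps original rows bit-identical. Originals come first in the output;
synthetic rows are appended and flagged, which is what makes the
pipeline's leakage audit possible.

## Feature selection

"Classic" permutation importance: fit the configured ensemble, measure
each column's mean accuracy drop over `n_repeats` shuffles (default 5),
clip negatives to zero, sort descending with name tie-breaks, and keep
the minimal prefix whose normalised cumulative importance reaches the
threshold (default 0.9). A published selected-feature count of this
style is also consistent with a keep-fraction reading, so
`mode="fraction"` (top `⌈0.9·m⌉` columns) is provided; cumulative is the
default because it adapts to how concentrated the importance mass is.
Selection runs strictly inside training data — refit per CV fold and on
the final training set, never on the holdout.

## Pipeline and evaluation

Defaults replicate the published protocol: encode → 100% SMOTE →
stratified 80/20 split → stratified 5-fold CV (mean ± SD) → final fit →
one holdout evaluation; global seed 123. `smote_order="before_split"`
is that protocol and is *knowingly leaky* — synthetic near-copies of
training rows land in validation folds and the holdout. The
`"train_only"` mode refits SMOTE inside each training fold and is the
recommended setting; per-fold audits count synthetic rows in validation
data, and the guarantee "zero in train_only mode" is asserted by tests.
Both modes log which protocol is running.

Classifier backends are external, configured implementations:
scikit-learn `ExtraTreesClassifier` with the published hyper-parameters
(200 trees, gini, depth 6, min split 7, min leaf 4, no bootstrap,
balanced-subsample weights), LightGBM with its published configuration,
and XGBoost as the second gradient-boosted variant (depth 6, 1000 rounds,
learning rate 0.01 — a symmetric-depth budget comparable to the boosted
model it stands in for). A small randomised grid tuner over documented
grids is optional.

Metrics implement the standard confusion-matrix closed forms plus the
rank-statistic ROC AUC (ties averaged; equivalent to Mann–Whitney) and
step-wise average precision over descending unique-score thresholds.
Zero-denominator metrics return 0 with a warning (the conservative
convention). Hard labels use a 0.5 probability threshold by default;
the threshold is configurable because published tables rarely state it.
Cross-validation summaries use the population SD across folds.

## Sequence statistics

Composition comparison averages per-peptide composition vectors per class
(each class mean sums to 1) and applies a Welch t-test per residue.
Position enrichment uses a 16-position window: positions 1–8 are the
first residues, positions 9–16 the last residues aligned to the C-
terminus. Each peptide contributes its first and last `min(8, N)`
residues, so peptides shorter than 16 contribute overlapping residues to
both windows — dropping them would bias composition. Per cell, occurrence
indicators are compared with a Welch t-test; when both classes are
constant the p-value is defined as 1 for equal means and 0 for complete
separation. No multiple-testing correction by default (matching the raw
p < 0.05 logo-scaling convention); Bonferroni is available. Because
cells are correlated (shared windows, within-position sum constraints),
the significant-cell *fraction* under the null has super-binomial
variance across simulations; calibration is therefore assessed on the
mean over replicate simulations, which the test suite measures as ≈0.05.

## Problem sizes used in tests and the acceptance script

Test problem sizes are chosen as the smallest that make each property
sharp: descriptor oracles on 200 random peptides (lengths 5–40), signal
recovery on 1000 peptides per run averaged over 5 seeds with AAC features
(the planted signal is purely compositional; SMOTE is off because the
classes are balanced there), null calibrations at 1000 peptides per
class. The acceptance script runs the full hybrid-feature pipeline at the
benchmark's 394/848 shape with `bias_strength = 1` and reports every
quantity it computes; selection there uses 2 permutation repeats over the
735 hybrid columns.

## Known limitations

- The synthetic generator plants only composition-level signal; models
  trained on it say nothing about attainable accuracy on real epitopes.
- The exact lag settings behind published hybrid-feature counts are not
  documented anywhere, so selected-feature counts are configuration-
  dependent and not comparable to any printed total.
- `before_split` SMOTE is provided for protocol replication; its metric
  estimates are optimistic by construction.
- Only binary labels and the 20 canonical residues are supported;
  ambiguity codes are rejected rather than imputed.
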