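# Methods

## Scope and model

chemosens trains one binary classifier per drug on a reference panel of
expression profiles (probe × sample log-scale intensities) with measured GI50
values, and scores new samples individually. The pipeline is: response
labeling → learning-set masking → stratified split → SVM-RFE feature
selection → final refit → LOOCV evaluation; prediction adds single-sample
quantile normalization in front of the decision function.

## Response labeling

GI50 values (molar) are transformed to y = −log₁₀(GI50), so larger values mean
higher sensitivity. Labels are sensitive (+1) for y > μ + h·σ, resistant (−1)
for y < μ − h·σ, indeterminate (0) otherwise, with h = 0.5 by default. Details
the underlying description leaves open, fixed here:

- σ is the sample standard deviation (n−1 denominator);
- values exactly on a threshold are indeterminate (strict inequalities);
- a zero-variance response vector yields all-indeterminate labels plus a
  warning rather than an error;
- missing GI50 entries are allowed in the response table and excluded per
  drug before labeling (drug panels are rarely complete).

Labels are invariant under increasing affine transformations of y, since the
thresholds are in SD units. Indeterminate samples are excluded from learning
(the learning mask requires at least two samples per retained class — an SVM
cannot be trained and validated below that); no mask applies at prediction.

## Classifier

Soft-margin linear SVM minimizing ½‖w‖² + C Σ hinge, with C = 1.0 by default
(the conventional box constraint; nothing in our experiments was sensitive to
it within 0.5–10). The fit is delegated to libsvm via scikit-learn with the
dual tolerance tightened to 1e−6, because the weight vector is consumed by
the elimination ranking and by exact analytic checks, not just by predictions.

Each training call learns per-feature center (mean) and spread (SD) on its
own training samples, fits in standardized space, and stores both vectors in
the model. Consequences: predictions are invariant to per-feature rescaling of
the raw data; a single query vector can be scored without a cohort; constant
features get spread 1 and (being uninformative) weight ≈ 0. Standardization is
re-learned at every RFE refit.

Orientation is semantic: the positive class is "sensitive", a strictly
positive decision score calls a responder, and a score of exactly 0 is a
non-responder. (The historical formulation of this decision function carries
a −1 factor compensating a toolbox-internal label ordering; we do not copy
the sign factor — orientation is defined by the class semantics instead.)

## Recursive feature elimination

Probes are ranked by |w| (the established relevance criterion for linear
SVM-RFE; signed-weight ranking would discard strong negative predictors).
Schedule: from the full probe count, remove the 100 lowest-ranked probes per
round; when fewer than 200 remain, remove exactly enough to land on 100; then
remove one probe at a time down to a floor of 10. Ties in |w| at an
elimination boundary drop the lexicographically larger probe ID first, making
runs deterministic.

The learning samples are split 75/25 stratified by class (seeded,
deterministic; rounding never empties a class in either partition), the same
split serving every step of one run. Each step's model is scored on the
validation part; the selected model maximizes validation accuracy with ties
broken toward the fewest features. The final model is refit on the training
partition restricted to the selected probes.

A note on redundancy: when several probes carry the same underlying signal,
weight-based elimination prunes them nearly as readily as noise — each
redundant copy has a small marginal weight given the others. The selected
model then mixes signal probes with a few chance-correlated survivors while
losing none of its accuracy. `rfe.ranking_recovery` therefore measures how a
*known* probe set concentrates in the top-k of the elimination ranking
(k = size of that set), which is the standard recovery score for feature
selection; on panels with strongly redundant planted probes it plateaus
around 0.5–0.6 even when LOOCV accuracy is near 1. This is a property of
SVM-RFE itself, not of the implementation.

## Single-sample normalization

The reference distribution is built once from the training matrix: quantile k
is the mean over reference arrays of each array's k-th smallest value (the
standard quantile-normalization target). Each query vector is mapped rank to
quantile independently of any other query ("one-by-one"); tied query values
receive the mean of the reference quantiles at the tied ranks, so the map is
deterministic and permutation-free. For tie-free queries the output is an
exact permutation of the target quantiles and the map is idempotent.

An alternative target built from sorted per-probe means is available
(`mode="probe-mean"`) for comparison but is not the default, the rank-mean
construction being what "standard quantile normalization" denotes. If a query
covers only part of the reference probe set, the target is rebuilt on the
intersection by linear interpolation of the reference quantile function at
the reduced number of ranks (with a logged warning); query probes unknown to
the reference are dropped with a logged count.

## Evaluation

- LOOCV refits the classifier per fold **over the already-selected probe
  set**. Re-running the feature selection inside every fold is not done by
  default: it multiplies cost by the schedule length and the single-pass
  selection is what the production model uses. The optimistic-bias caveat is
  real — selection has seen every learning sample — and LOOCV numbers should
  be read as in-panel consistency, not unbiased generalization estimates.
- `roc_auc` is a threshold sweep; its trapezoidal area equals the
  Mann–Whitney concordance probability with ties counted ½ (tested against
  exhaustive pair counting). `balanced_accuracy_auc` is the distinct
  single-operating-point quantity (tpr − fpr + 1)/2, kept under that name for
  fidelity with the platform's published description; the two agree only for
  separable two-point score distributions.
- Quadrant concordance compares sign(score) with sign(y − ȳ) where ȳ is the
  mean −log₁₀(GI50) of the evaluated samples; samples exactly at the mean are
  excluded.
- The cohort response rate is the fraction of query samples with strictly
  positive scores; `rate_regression` is ordinary least squares of observed on
  predicted rates with R² the squared Pearson correlation.

## Synthetic panels

`SyntheticSpec` defaults describe the reference study conditions: 60 samples,
2000 probes, 20 informative probes, effect size 2 (per unit of latent
sensitivity, in units of the probe noise SD), log2-intensity baselines
N(8, 1.5²), unit probe noise, and −log₁₀(GI50) = 6 + 1·s + ε with
ε ~ N(0, 0.3²), where s ~ N(0,1) is each sample's latent sensitivity. GI50 is
therefore log-normal and its −log transform normal (checked by Shapiro–Wilk
across seeds). Informative probes read `baseline + effect·s + noise`; with
`probes_per_gene > 1` the informative probes are placed one per gene, so
gene-averaging dilutes an isoform-specific signal. Tissue panels add a per
probe × tissue baseline offset (SD `tissue_sd`) and, optionally, a per-tissue
shift of the latent sensitivity (`tissue_response_sd`, default 0) reflecting
that drug response clusters by tissue of origin in real cell-line panels.

What the generator does **not** emulate: probe–probe correlation structure
beyond the planted signal, intensity-dependent noise, array artifacts,
platform differences, or dose–response curve fitting. Passing tests therefore
demonstrate the pipeline's statistical machinery, not clinical performance.

### Design experiments (sizes chosen for mechanism and runtime)

- **Tissue diversity**: 126 samples in 9 tissue blocks (probe space 300, 15
  informative at effect 2, tissue offset SD 1.5, tissue response shift 0.8).
  The first 3 samples of each block form a common test set; one model trains
  on the determinate samples of 2 blocks, the other on an equal number drawn
  round-robin from all 9. With tissue correlated to response, the narrow
  learning set lets tissue-marker probes masquerade as predictors that fail
  off-tissue; diverse training averages the confounding away. Mean held-out
  accuracy over 20 seeds: ≈0.87 (diverse) vs ≈0.77 (narrow).
- **Probe-level vs gene-averaged**: 600 probes in 200 genes (3 probes/gene),
  15 informative genes with exactly one informative probe each; comparing
  LOOCV accuracy of the probe-level fit against the same fit on gene-mean
  collapsed features (≈0.99 vs ≈0.95 over 20 seeds).
- **Pre-filtering**: 400 probes, 12 informative; the filtered condition
  restricts the starting set to exclude half of the informative probes
  (≈0.98 vs ≈0.96 over 20 seeds).

## Reproducibility

All randomness flows through explicit integer seeds (panel generation and the
train/validation split); libsvm is deterministic given its inputs. Model
files are plain text with floats serialized via `repr`, so write→read is the
identity to full float64 precision and identical config+seed reproduce
byte-identical model files. Each pipeline run writes a manifest with the
config, seed and SHA-256 checksums of its inputs.

## Known limitations

- LOOCV does not re-run feature selection per fold (see above); nested
  selection is a straightforward extension but changes the cost profile.
- The indeterminate band, split fraction, block size and feature floor are
  guarded constants; lowering the floor below 10 requires an explicit
  `allow_nonpaper` override.
- Quantile normalization assumes the query measures (close to) the reference
  probe set; heavy probe loss degrades the interpolated target.
- Recovery of redundant informative probe sets by weight-based RFE saturates
  well below 100% by construction (see the RFE section).
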