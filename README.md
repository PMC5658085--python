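# chemosens

Drug-response prediction from gene expression profiles, for researchers who
want to train chemosensitivity classifiers on a reference cell-line panel and
score new tumor samples one at a time.

Given a probe × sample log-intensity matrix and per-sample GI50 values (the
molar drug concentration inhibiting growth by 50%), the package builds a
per-drug linear support-vector-machine classifier with recursive feature
elimination (SVM-RFE), and applies it to new expression profiles after
single-sample quantile normalization against the training reference. It is a
self-contained, text-format reimplementation of an open-source
precision-oncology workflow, with a synthetic-data generator so every stage is
testable without external data.

## The method

**Labels.** Working with y = −log₁₀(GI50) (higher ⇒ more sensitive), samples
are trifurcated around the cohort mean: sensitive (+1) if y > μ + 0.5σ,
resistant (−1) if y < μ − 0.5σ, indeterminate (0) inside the band.
Indeterminate samples are excluded from learning but not from prediction.

**Classifier.** A soft-margin linear SVM separates the two classes with the
hyperplane w·x + b = 0 minimizing ½‖w‖² + C Σᵢ max(0, 1 − yᵢ(w·xᵢ + b)),
C = 1 by default. Features are standardized inside training and the
standardization is stored in the model, so a single query sample can be
scored with no cohort context. A sample is called a **responder** iff its
decision score w·x̃ + b is strictly positive.

**Feature selection.** RFE: train, rank probes by |w|, drop the bottom 100,
repeat until 100 probes remain, then drop one at a time down to a floor of 10.
Each step's model is scored on a held-out stratified validation split (25% of
the learning samples); the model with the highest validation accuracy wins,
ties going to the fewest features.

**Normalization.** New arrays are quantile-normalized **one by one** against
a fixed target distribution — the rank-wise mean of the sorted reference
arrays — so a sample's normalized values never depend on which other samples
arrive with it.

**Evaluation.** Leave-one-out cross-validation over the selected probe set,
confusion metrics, threshold-sweep ROC/AUC (plus the single-operating-point
balanced accuracy (tpr − fpr + 1)/2 under the name `balanced_accuracy_auc`),
quadrant concordance of scores against −log₁₀(GI50), and cohort response
rates.

## Worked example

```python
from chemosens import DrugResponseModel, SyntheticSpec, generate

spec = SyntheticSpec(n_samples=60, n_probes=2000, n_informative=20,
                     effect_size=2.0, seed=7)
expr, gi50, truth = generate(spec)          # probes x samples, samples x drugs
results = DrugResponseModel(expr, gi50, "drugA").fit(seed=7)
print(results.summary())
```

```
Drug response model — drugA
======================================================
samples: 60  (sensitive 18, resistant 19, indeterminate 23)
-log10(GI50): mean 5.7507, SD 0.9025, band ±0.5·SD
starting probes: 2000
RFE steps: 110; selected 500 features at validation accuracy 1.000
C = 1.0, split = 75%, seed = 7
------------------------------------------------------
LOOCV (n=37): accuracy 0.973, sensitivity 0.944, specificity 1.000, AUC 1.000
```

Of the 60 cell lines, 23 fall inside the ±0.5 SD indeterminate band and are
excluded from learning; the RFE trace visits 110 feature counts and selects
the smallest set that maximizes validation accuracy. LOOCV then refits the
selected probe set once per held-out sample: 36 of 37 determinate lines are
called correctly. Scoring a query cohort (normalized one-by-one against the
training reference):

```python
pred = results.predict(expr.iloc[:, :5])
print(pred)                                  # sample_id, drug, score, call
print(results.response_rate(expr.iloc[:, :5]))
```

```
sample_id  drug     score          call
    CL000 drugA -0.049116 non-responder
    CL001 drugA  0.045276     responder
    ...
0.2
```

Positive scores predict sensitivity; the response rate is the responder
fraction of the cohort.

The same workflow is available from the shell:

```bash
chemosens simulate --outdir fx --seed 7
chemosens train --expression fx/expression.tsv --responses fx/gi50.tsv \
                --drug drugA --seed 7 --outdir run
chemosens predict --model run/drugA.model.txt --input fx/expression.tsv \
                  --reference fx/expression.tsv --output pred.tsv
```

Every training run writes a manifest (config, seed, input checksums); reruns
with an identical manifest produce byte-identical model files.

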