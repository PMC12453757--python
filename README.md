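# psonet

A particle-swarm-optimized neural network for binary diagnostic
classification from tabular biomedical features — built for studies of
Parkinson's disease prediction from voice biomarkers (jitter, shimmer,
harmonics-to-noise measures) and mixed demographic/clinical assessments,
but applicable to any two-class tabular problem.

## The method

Instead of backpropagation, a single-hidden-layer network (ReLU hidden
layer, softmax output, two output nodes) is trained by **particle swarm
optimization (PSO)**. Every particle *i* occupies a position
**x**ᵢ — a flat vector of all the network's weights and biases
(D = p·h + h + 2h + 2 dimensions) — and moves according to the standard
update equations

    vᵢ ← w·vᵢ + c₁ r₁ ∘ (pbestᵢ − xᵢ) + c₂ r₂ ∘ (gbest − xᵢ)
    xᵢ ← xᵢ + vᵢ

with per-dimension uniform random factors r₁, r₂, velocity clamping at
±v_max, a particle-personal best `pbest` and the swarm-global best
`gbest`. The fitness minimized is the mean negative log-likelihood on
training data plus an L2 penalty λ·Σw² on the weights. The inertia
weight w is either constant (0.9) or decays linearly from 0.9 to 0.4
over the run. Training runs in epochs of swarm iterations with early
stopping on a monitored loss (patience 10, up to 1000 epochs).

Around that core the package provides the full study pipeline:

* `psonet.preprocess` — CSV loading, SMOTE minority oversampling
  (segment interpolation to k-nearest minority neighbours), stratified
  train/test splitting, train-fitted standardization;
* `psonet.metrics` — confusion matrix, accuracy, sensitivity TP/(TP+FN),
  specificity TN/(TN+FP), balanced accuracy, per-class/macro/weighted
  precision-recall-F1, ROC and trapezoidal AUC;
* `psonet.feature_select` — ANOVA F, chi-squared, mutual information,
  variance filtering, recursive feature elimination with a pluggable
  ranker, importance thresholding, and correlation-strength
  categorization (|r| > 0.6 high, 0.4–0.6 moderate, 0.2–0.4 low,
  ≤ 0.2 minimal);
* `psonet.evaluate` — stratified k-fold cross-validation, paired t and
  Wilcoxon signed-rank model comparison, adapters for scikit-learn
  baselines;
* `psonet.synthetic_data` — seeded generators for voice-like and
  clinical-like datasets, so the whole pipeline is testable without any
  dataset download.

## Worked example

Generate a synthetic voice-style dataset (400 recordings, 8 acoustic
features, 75 % positive class, 1.5-SD class separation) and train a
small swarm model on it:

```bash
psonet simulate --kind voice --n-samples 400 --n-features 8 \
    --class1-fraction 0.75 --mean-shift 1.5 --seed 1 --out demo.csv
psonet train --data demo.csv --target status --out-dir demo_run \
    --n-hidden 32 --swarm-size 30 --max-epochs 60 \
    --iterations-per-epoch 5 --patience 5 --seed 0
```

which prints (abridged):

```
                precision    recall  f1-score  support

       class 0       0.91      1.00      0.95       20
       class 1       1.00      0.97      0.98       60

Confusion matrix (rows: true 0/1, cols: predicted 0/1)
  [[    20      0]
   [     2     58]]

Accuracy            0.9750
Balanced accuracy   0.9833
Sensitivity         0.9667
Specificity         1.0000
AUC                 0.9983
```

Read: of the 80 held-out samples the model misses two positive cases
(sensitivity 0.9667) and produces no false alarms (specificity 1.0);
the AUC of 0.998 says a random positive case outscores a random
negative one 99.8 % of the time. `demo_run/` contains the fully
resolved `config.json` (every default and seed), `metrics.json`, the
ROC point series as CSV, the text report, per-sample predictions, and
the per-epoch training history — enough to replay the run exactly.

By default the pipeline is leakage-free: the split happens first, and
SMOTE plus the early-stopping validation carve touch only the training
partition. `--paper-mode` switches to the commonly published (but leaky)
ordering — SMOTE on the full table before splitting, early stopping
monitored on the test set — for replication studies.

Other subcommands: `psonet evaluate` (k-fold CV of the swarm model),
`psonet select-features`, `psonet compare` (CV comparison against
scikit-learn baselines with fold-paired significance tests), and
`psonet report` (re-render metrics from stored predictions).

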