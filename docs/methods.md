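# Methods

## Model

The classifier is a single-hidden-layer feed-forward network: p input
nodes (one per feature), h hidden ReLU units (default 256), and a
two-node softmax output for the binary decision. All weights and biases
are concatenated into one flat parameter vector of dimension
D = p·h + h + 2h + 2 (6402 for the 22-feature voice configuration); the
codec in `network.py` maps between this vector and the layer matrices
and is an exact round trip.

No gradients are used. The vector is searched by particle swarm
optimization: a population of candidate vectors moves under inertia,
attraction to each particle's personal best, and attraction to the
swarm's global best. Fitness is the mean negative log-likelihood of the
training labels plus an L2 penalty:

    L(θ) = −(1/n) Σᵢ log p(yᵢ | xᵢ, θ) + λ Σ w²

Conventions that the literature often leaves unstated, fixed here so
results are reproducible:

* the penalty covers weights only, not biases, and carries no ½ factor;
* the NLL is a mean over samples, not a sum;
* predicted probabilities are clipped at 1e-12 before the log, so the
  loss stays finite under the extreme weight vectors a swarm explores;
* a 0.5/0.5 predicted tie resolves to class 1 (the disease class) —
  the clinically conservative choice, favouring sensitivity.

Inverted dropout on the hidden layer (rate 0.5 by default) is available
for stochastic fitness evaluation but is **off** by default
(`dropout_in_fitness=False`): with deterministic fitness the global-best
loss is provably non-increasing, which the tests rely on, and swarm
training does not need dropout's gradient-noise role. When enabled, a
fresh mask is drawn per swarm-step evaluation from the swarm's seeded
stream, shared by all particles within that step.

## Swarm parameters

| parameter | default | meaning |
|---|---|---|
| swarm_size | 100 | particles in the population |
| c₁, c₂ | 0.5, 0.3 | cognitive / social attraction coefficients |
| inertia_mode | constant | `constant` holds w = w_start; `linear_decay` interpolates w_start → w_end |
| w_start, w_end | 0.9, 0.4 | inertia endpoints (dimensionless) |
| v_max | 1.0 | per-component velocity clamp; set equal to the init range width |
| init_low, init_high | 0.0, 1.0 | uniform position initialization box |
| iterations_per_epoch | 10 | swarm steps between monitor evaluations |
| max_epochs | 1000 | training horizon |
| patience | 10 | epochs without monitored-loss improvement before stopping |
| tol | 1e-6 | absolute improvement threshold for "no improvement" |
| λ (l2_lambda) | 0.01 | L2 penalty strength |

Design points that were genuinely open:

* **Inertia.** Constant w = 0.9 is the default operating mode; the
  linear 0.9 → 0.4 decay schedule is implemented and exposed because it
  is the canonical convergence configuration. Convergence-oriented runs
  (the sphere-function benchmarks in the tests) use decay mode; training
  runs use the constant default.
* **Random factors** r₁, r₂ are drawn per dimension (the canonical
  reading of the update equation), not one scalar per particle.
* **Positions are never clamped** after initialization. Weights must be
  able to leave the [0, 1] initialization box to fit standardized
  (zero-mean) features; only velocities are clamped.
* **Ordering within a step**: fitness is evaluated and bests updated
  *before* velocities and positions move, so the reported gbest always
  refers to an actually-evaluated position.
* **Epochs**: one "epoch" is a block of `iterations_per_epoch` swarm
  steps followed by one monitor evaluation. Ten steps per epoch balances
  monitor overhead against stopping granularity.
* The early-stopping counter treats any improvement ≤ tol as a stall;
  the run returns the global-best vector, the per-epoch history, the
  stopping epoch and the reason.

## Preprocessing

SMOTE generates each synthetic minority sample on the segment between a
random minority point and one of its k nearest minority neighbours
(k = 5, the original convention): x_new = x + u·(x_nn − x),
u ~ U(0, 1). Original rows are never modified. By default the pipeline
splits **first** and applies SMOTE only to the training partition;
early stopping monitors a validation split carved from training
(fraction 0.2). The published order — SMOTE on the pooled table before
splitting, early stopping on the test set — leaks synthetic copies of
test information into training and is available only behind the
explicit `paper_mode` flag for replication.

Standardization is fit on training data only and uses the population
(divide-by-n) SD convention; a zero-variance training feature is an
error (variance-filter first). Splits are stratified by default;
test_fraction 0.2, split seed 42.

## Synthetic data

The generators emulate the *statistical shape* of two dataset families,
not any real data values:

* **voice-like** — continuous acoustic-style features (named from the
  classic jitter/shimmer/HNR vocabulary), imbalanced classes (the UCI
  voice benchmark is roughly 3:1 positive), positively correlated
  feature blocks, class-1 means shifted by a configurable number of
  feature SDs;
* **clinical-like** — a larger mixed table adding {0, 1} columns drawn
  as class-dependent Bernoulli variables (e.g. comorbidity flags).

Labels are assigned first so class counts are exact
(round(n·class1_fraction)); features are sampled conditionally from a
multivariate normal with block-constant correlation; flagged columns are
exponentiated to obtain the heavy right skew of jitter-like
measurements. Everything is driven by one seed; identical specs produce
bit-identical tables.

What the generators deliberately do **not** reproduce: real marginal
distributions, the published per-feature summary statistics, real
correlation values, measurement artefacts, or within-subject repeated
recordings. Consequently, a passing pipeline on synthetic data shows
the machinery is correct and can learn a planted signal of a stated
size — it does not certify clinical performance on real recordings.

The study-condition checks use: a strong-signal table (2-SD mean shift,
n = 600, 22 features, 3:1 imbalance) on which the full-default pipeline
must reach ≥ 0.95 test accuracy, and a null table (zero shift,
n = 2000) on which test AUC must sit within 0.5 ± 0.05. n = 2000 for
the null check gives a 400-sample test set, small enough to run quickly
and large enough that the AUC sampling SD (~0.03) resolves the band.

## Metrics

All scalar metrics derive from the 2×2 confusion matrix with class 1
positive. Zero-denominator cases (e.g. a majority-class predictor with
no predicted positives) return 0.0 with a `degenerate` flag instead of
raising, so trivial baselines remain representable in comparison
tables. The ROC curve is built over all distinct score thresholds with
ties grouped; the trapezoidal AUC then equals the Mann–Whitney
probability P(s⁺ > s⁻) + ½P(s⁺ = s⁻), which the tests verify against
O(n²) pair counting. Reports render class rows at 2 decimals and
summary rows at 4, with full precision kept internally.

## Feature selection

Filter scores are computed from their defining formulas: two-group
one-way ANOVA F; the classic chi-squared selector on class-wise feature
sums (non-negative features required); plug-in mutual information in
nats over equal-frequency bins (default 10 — deterministic, no RNG,
unlike nearest-neighbour MI estimators); population variance. RFE takes
any ranker callable and drops the `step` weakest survivors per refit
round; a dependency-free decision-stump ranker (best single-threshold
accuracy gain) ships for self-contained use, while forest importances
plug in through the same contract. Correlation categories use closed
upper bounds: exactly 0.6 is "moderate", exactly 0.4 is "low".

## Model comparison

k-fold CV (stratified, seeded) produces per-fold metric vectors; each
candidate is compared to the reference model with a paired t-test on
accuracy and a Wilcoxon signed-rank test on weighted F1, both
two-sided. The Wilcoxon p-value is exact for n ≤ 25 (null distribution
of the positive-rank sum by convolution over all sign assignments,
midranks for ties) and a tie-corrected normal approximation beyond.
Note that with k-fold pairing both tests have only n = k observations;
on a perfectly separated dataset all fold differences can coincide,
which makes the paired t degenerate — the harness reports this instead
of fabricating a p-value. Wall time is reported but is
hardware-dependent and never part of any assertion.

## Known limitations

* Fitness evaluation is batched across particles (two large matrix
  products per swarm step); memory scales as swarm_size × n × h floats.
* The L2 term dominates the fitness for large networks at
  initialization, so early search mostly shrinks weights; with strong
  class signal this does not prevent the NLL term from driving the
  decision boundary, but λ should be reduced for weak-signal problems.
* Only binary classification; one hidden layer; no gradient refinement.
* The comparison harness treats folds as the pairing unit; conclusions
  from k = 5 paired tests are accordingly low-powered.
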