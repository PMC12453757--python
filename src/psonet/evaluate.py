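"""Cross-validation, paired statistical model comparison, and adapters.

The harness evaluates any model exposing the two-method contract
``fit(train_table)`` / ``predict_scores(test_table) -> (labels, scores)``.
:class:`PsoNetModel` wraps this package's swarm-trained network in that
contract; :class:`SklearnAdapter` wraps any scikit-learn classifier so
external baselines can sit in the same comparison table.

Model comparison follows the usual fold-paired design: k-fold CV produces
per-fold metric vectors, and candidate models are compared to a reference
with a paired t-test on accuracy and a Wilcoxon signed-rank test on F1.
Both test statistics are computed here from their definitions (exact
sign-assignment enumeration for the Wilcoxon null up to n=25); only the
reference distributions (Student t, normal) come from scipy.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold

from . import metrics as metrics_mod
from . import network, pso
from .metrics import MetricsReport
from .network import NetworkSpec
from .preprocess import FeatureTable, smote_oversample, split_train_test, standardize
from .pso import SwarmConfig

__all__ = [
    "FoldMetrics",
    "PairedTestResult",
    "ComparisonResult",
    "kfold_cv",
    "paired_t_test",
    "wilcoxon_signed_rank",
    "compare_models",
    "PsoNetModel",
    "SklearnAdapter",
    "MajorityClassModel",
]


@dataclass
class FoldMetrics:
    fold_index: int  # 1-based
    report: MetricsReport
    train_time: float


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n: int
    method: str  # "paired_t" | "wilcoxon_signed_rank"


def kfold_cv(
    model_factory,
    table: FeatureTable,
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> list[FoldMetrics]:
    """k-fold cross-validation of a model factory.

    Folds are disjoint, cover the table, and differ in size by at most
    one row; assignment is deterministic per seed. ``model_factory()``
    must return a fresh unfitted model each call.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > table.n_samples:
        raise ValueError(f"k={k} exceeds n={table.n_samples}")
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    results = []
    split_args = (table.features, table.labels) if stratified else (table.features,)
    for fold_index, (train_idx, test_idx) in enumerate(splitter.split(*split_args), 1):
        train = table.subset(train_idx)
        test = table.subset(test_idx)
        if stratified and (len(set(test.labels)) < 2 or len(set(train.labels)) < 2):
            raise ValueError(f"fold {fold_index} empties a class")
        model = model_factory()
        t0 = time.perf_counter()
        model.fit(train)
        elapsed = time.perf_counter() - t0
        labels, scores = model.predict_scores(test)
        # AUC is undefined on a single-class fold (e.g. leave-one-out)
        scores_arg = scores if len(np.unique(test.labels)) == 2 else None
        report = metrics_mod.classification_report(test.labels, labels, scores_arg)
        results.append(FoldMetrics(fold_index, report, elapsed))
    return results


def paired_t_test(a, b) -> PairedTestResult:
    """Two-sided paired t-test on matched measurement vectors.

    t = mean(d) / (sd(d) / sqrt(n)) with the sample (n-1) SD; p from the
    t distribution with n-1 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal-length")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("all paired differences identical; t-test degenerate")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(float(t), float(p), n, "paired_t")


def _wilcoxon_exact_p(ranks2: np.ndarray, w_plus2: int) -> float:
    """Exact two-sided p by enumerating all sign assignments.

    ``ranks2`` are midranks doubled to integers; the null distribution of
    the doubled positive-rank sum is built by convolution over the 2^n
    sign patterns.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[: w_plus2 + 1].sum()
    p_ge = counts[w_plus2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def wilcoxon_signed_rank(a, b) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on matched vectors.

    Zero differences are dropped; |d| is ranked with midranks for ties;
    the statistic is W = min(W+, W-). The p-value is exact (sign-pattern
    enumeration) for n <= 25, else a normal approximation with tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal-length")
    d = a - b
    d = d[d != 0]
    n = d.shape[0]
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= 25:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _wilcoxon_exact_p(ranks2, int(round(2 * w_plus)))
    else:
        mean = n * (n + 1) / 4
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24 - ((tie_counts**3 - tie_counts).sum()) / 48
        z = (w_plus - mean) / np.sqrt(var)
        p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    return PairedTestResult(float(w), p, n, "wilcoxon_signed_rank")


# ---------------------------------------------------------------------------
# model adapters


class PsoNetModel:
    """Swarm-trained network behind the fit/predict-score contract.

    ``fit`` optionally SMOTE-balances the training part, carves a
    validation split (``val_fraction``) to monitor early stopping,
    standardizes on training statistics, and runs the swarm; prediction
    reapplies the stored scaler.
    """

    name = "PSO-NN"

    def __init__(
        self,
        n_hidden: int = 256,
        l2_lambda: float = 0.01,
        dropout_rate: float = 0.5,
        swarm_config: SwarmConfig | None = None,
        val_fraction: float = 0.2,
        apply_smote: bool = True,
        smote_k: int = 5,
        seed: int = 0,
        monitor_table: FeatureTable | None = None,
    ):
        self.n_hidden = n_hidden
        self.l2_lambda = l2_lambda
        self.dropout_rate = dropout_rate
        self.swarm_config = swarm_config or SwarmConfig(seed=seed)
        self.val_fraction = val_fraction
        self.apply_smote = apply_smote
        self.smote_k = smote_k
        self.seed = seed
        self.monitor_table = monitor_table  # overrides the validation carve
        self.result_: pso.TrainResult | None = None

    def fit(self, train: FeatureTable) -> "PsoNetModel":
        if self.apply_smote:
            counts = train.class_counts()
            if min(counts.values()) > self.smote_k and counts[0] != counts[1]:
                train = smote_oversample(train, self.smote_k, 1.0, self.seed)
        if self.monitor_table is not None:
            fit_part, monitor = train, self.monitor_table
        else:
            fit_part, monitor = split_train_test(
                train, self.val_fraction, self.seed, stratified=True
            )
        fit_std, monitor_std, self.scaler_ = standardize(fit_part, monitor)
        self.spec_ = NetworkSpec(
            n_input=train.n_features,
            n_hidden=self.n_hidden,
            dropout_rate=self.dropout_rate,
            l2_lambda=self.l2_lambda,
        )
        self.result_ = pso.train(fit_std, monitor_std, self.spec_, self.swarm_config)
        return self

    def predict_scores(self, table: FeatureTable):
        if self.result_ is None:
            raise RuntimeError("model is not fitted")
        X = self.scaler_.transform(table.features)
        return network.predict(self.result_.best_params, X, self.spec_)


class SklearnAdapter:
    """Wrap any scikit-learn classifier into the comparison contract."""

    def __init__(self, name: str, estimator, standardize_features: bool = True):
        self.name = name
        self.estimator = estimator
        self.standardize_features = standardize_features

    def fit(self, train: FeatureTable) -> "SklearnAdapter":
        X = train.features
        if self.standardize_features:
            self.mean_ = X.mean(axis=0)
            self.sd_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
            X = (X - self.mean_) / self.sd_
        self.model_ = clone(self.estimator).fit(X, train.labels)
        return self

    def predict_scores(self, table: FeatureTable):
        X = table.features
        if self.standardize_features:
            X = (X - self.mean_) / self.sd_
        labels = self.model_.predict(X)
        if hasattr(self.model_, "predict_proba"):
            scores = self.model_.predict_proba(X)[:, 1]
        elif hasattr(self.model_, "decision_function"):
            scores = self.model_.decision_function(X)
        else:
            scores = labels.astype(float)
        return labels, scores


class MajorityClassModel:
    """Predicts the majority training class everywhere (dummy baseline).

    Its balanced accuracy is 0.5 by construction and its AUC 0.5 (constant
    scores) — the floor any learned model must beat.
    """

    name = "DummyClassifier"

    def fit(self, train: FeatureTable) -> "MajorityClassModel":
        counts = train.class_counts()
        self.majority_ = 1 if counts[1] >= counts[0] else 0
        return self

    def predict_scores(self, table: FeatureTable):
        n = table.n_samples
        return np.full(n, self.majority_, dtype=int), np.full(n, 0.5)


@dataclass
class ComparisonResult:
    """Comparison table plus fold-paired tests against the reference model.

    ``table`` has one row per model (mean CV metrics, wall time), sorted
    by accuracy with a lexical name tie-break. ``tests[name]`` holds the
    paired t on accuracy and the Wilcoxon on F1 for model ``name`` vs the
    reference. Models whose adapter raised are listed in ``failures``.
    """

    table: pd.DataFrame
    fold_metrics: dict[str, list[FoldMetrics]]
    tests: dict[str, dict[str, PairedTestResult]]
    failures: dict[str, str]
    reference: str


def compare_models(
    adapters: list,
    table: FeatureTable,
    k: int = 5,
    seed: int = 0,
    reference: str | None = None,
) -> ComparisonResult:
    """Cross-validated comparison of a model roster.

    Every adapter is evaluated on the same fold assignment; the reference
    (default: the first adapter) is compared to each other model with a
    paired t-test on per-fold accuracy and a Wilcoxon signed-rank test on
    per-fold weighted F1.
    """
    if not adapters:
        raise ValueError("empty model roster")
    reference = reference or adapters[0].name
    fold_metrics: dict[str, list[FoldMetrics]] = {}
    failures: dict[str, str] = {}
    rows = []
    for adapter in adapters:
        try:
            folds = kfold_cv(lambda a=adapter: a, table, k=k, seed=seed)
        except Exception as exc:  # adapter failure is isolated, not fatal
            failures[adapter.name] = f"{type(exc).__name__}: {exc}"
            continue
        fold_metrics[adapter.name] = folds
        rows.append({
            "model": adapter.name,
            "accuracy": np.mean([f.report.accuracy for f in folds]),
            "balanced_accuracy": np.mean([f.report.balanced_accuracy for f in folds]),
            "roc_auc": np.mean([f.report.auc for f in folds]),
            "f1": np.mean([f.report.weighted_f1 for f in folds]),
            "time_s": np.sum([f.train_time for f in folds]),
        })
    df = (
        pd.DataFrame(rows)
        .sort_values(["accuracy", "model"], ascending=[False, True])
        .reset_index(drop=True)
    )
    tests: dict[str, dict[str, PairedTestResult]] = {}
    if reference in fold_metrics and len(fold_metrics) > 1:
        ref_acc = [f.report.accuracy for f in fold_metrics[reference]]
        ref_f1 = [f.report.weighted_f1 for f in fold_metrics[reference]]
        for name, folds in fold_metrics.items():
            if name == reference:
                continue
            acc = [f.report.accuracy for f in folds]
            f1 = [f.report.weighted_f1 for f in folds]
            entry: dict[str, PairedTestResult] = {}
            try:
                entry["accuracy_paired_t"] = paired_t_test(ref_acc, acc)
            except ValueError as exc:
                failures.setdefault(name, f"paired t degenerate: {exc}")
            try:
                entry["f1_wilcoxon"] = wilcoxon_signed_rank(ref_f1, f1)
            except ValueError as exc:
                failures.setdefault(name, f"wilcoxon degenerate: {exc}")
            tests[name] = entry
    return ComparisonResult(df, fold_metrics, tests, failures, reference)
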