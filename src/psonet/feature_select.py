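"""Filter and wrapper feature-selection battery plus the correlation-
strength categorization used for clinical interpretation.

Filter scores (ANOVA F, chi-squared, mutual information, variance) are
computed directly from their defining formulas so they are deterministic
and easy to audit; the wrapper methods (recursive feature elimination,
importance thresholding) take any ranking callable, so model-based
rankers — e.g. a random forest's impurity importances — plug in through
the same contract. A self-contained decision-stump ranker ships for
testing and small studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import FeatureTable

__all__ = [
    "FeatureScores",
    "anova_f_scores",
    "mutual_information_scores",
    "chi2_scores",
    "variance_filter",
    "rfe",
    "select_from_importance",
    "correlation_categorize",
    "stump_importance",
]


@dataclass
class FeatureScores:
    """Per-feature scores from one selection method.

    ``selected`` marks the features the method keeps; ``top(k)`` returns
    the k highest-scoring names.
    """

    feature_names: list[str]
    scores: np.ndarray
    method: str
    selected: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.selected = np.asarray(self.selected, dtype=bool)
        if not len(self.feature_names) == len(self.scores) == len(self.selected):
            raise ValueError("feature_names, scores and selected must align")

    def top(self, k: int = 5) -> list[str]:
        order = np.argsort(-self.scores, kind="stable")
        return [self.feature_names[i] for i in order[:k]]


def _split_by_class(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    X0 = table.features[table.labels == 0]
    X1 = table.features[table.labels == 1]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("each class needs at least 2 samples")
    return X0, X1


def anova_f_scores(table: FeatureTable) -> FeatureScores:
    """One-way ANOVA F statistic of each feature against the two label
    groups: between-group mean square over within-group mean square.

    A feature with zero within-group variance but distinct group means
    scores +inf and ranks first.
    """
    X0, X1 = _split_by_class(table)
    n0, n1 = len(X0), len(X1)
    n = n0 + n1
    grand = table.features.mean(axis=0)
    ssb = n0 * (X0.mean(axis=0) - grand) ** 2 + n1 * (X1.mean(axis=0) - grand) ** 2
    ssw = ((X0 - X0.mean(axis=0)) ** 2).sum(axis=0) + ((X1 - X1.mean(axis=0)) ** 2).sum(axis=0)
    msb = ssb / 1.0  # k - 1 = 1 group degree of freedom
    msw = ssw / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(msw > 0, msb / msw, np.where(msb > 0, np.inf, 0.0))
    return FeatureScores(list(table.feature_names), f, "anova_f", np.ones(len(f), bool))


def mutual_information_scores(table: FeatureTable, n_bins: int = 10) -> FeatureScores:
    """Plug-in mutual information (nats) between each discretized feature
    and the label.

    Features are discretized by equal-frequency binning (deterministic, no
    RNG); a feature with a single distinct value has MI 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    y = table.labels
    n = table.n_samples
    p_y = np.array([np.mean(y == 0), np.mean(y == 1)])
    mi = np.zeros(table.n_features)
    for j in range(table.n_features):
        x = table.features[:, j]
        interior = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
        bins = np.searchsorted(interior, x, side="right")
        if len(np.unique(bins)) < 2:  # effectively constant feature
            continue
        total = 0.0
        for b in np.unique(bins):
            in_bin = bins == b
            p_x = in_bin.mean()
            for cls in (0, 1):
                p_xy = np.mean(in_bin & (y == cls))
                if p_xy > 0:
                    total += p_xy * np.log(p_xy / (p_x * p_y[cls]))
        mi[j] = max(total, 0.0)
    return FeatureScores(list(table.feature_names), mi, "mutual_information",
                         np.ones(table.n_features, bool))


def chi2_scores(table: FeatureTable) -> FeatureScores:
    """Classic chi-squared selector: per-feature chi2 of observed
    class-wise feature sums against the expectation under label
    independence. Requires non-negative feature values."""
    if np.any(table.features < 0):
        raise ValueError(
            "chi-squared selector requires non-negative features; "
            "min-max rescale the table first"
        )
    y = table.labels
    observed = np.stack([
        table.features[y == 0].sum(axis=0),
        table.features[y == 1].sum(axis=0),
    ])  # (2, p)
    class_prob = np.array([np.mean(y == 0), np.mean(y == 1)])[:, None]
    expected = class_prob * table.features.sum(axis=0)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    chi2 = terms.sum(axis=0)
    return FeatureScores(list(table.feature_names), chi2, "chi2",
                         np.ones(table.n_features, bool))


def variance_filter(table: FeatureTable, threshold: float = 0.0) -> FeatureScores:
    """Population variance per feature; selected iff variance > threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    var = table.features.var(axis=0)  # population convention
    return FeatureScores(list(table.feature_names), var, "variance", var > threshold)


def rfe(ranker, table: FeatureTable, n_keep: int, step: int = 1) -> FeatureScores:
    """Recursive feature elimination with a generic ranker.

    Each round the ranker is refit on the surviving columns and the
    ``step`` lowest-importance survivors are dropped (the final round is
    truncated so exactly ``n_keep`` remain). Scores record the elimination
    order: survivors share the highest rank, earlier-dropped features rank
    lower.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be at least 1")
    if step < 1:
        raise ValueError("step must be at least 1")
    p = table.n_features
    surviving = list(range(p))
    rank = np.zeros(p)
    round_no = 0
    while len(surviving) > n_keep:
        round_no += 1
        sub = FeatureTable(
            table.features[:, surviving],
            [table.feature_names[i] for i in surviving],
            table.labels,
        )
        importance = np.asarray(ranker(sub), dtype=float)
        if importance.shape != (len(surviving),):
            raise ValueError(
                f"ranker returned {importance.shape} importances for "
                f"{len(surviving)} features"
            )
        n_drop = min(step, len(surviving) - n_keep)
        drop_local = np.argsort(importance, kind="stable")[:n_drop]
        for loc in drop_local:
            rank[surviving[loc]] = round_no
        surviving = [f for loc, f in enumerate(surviving) if loc not in set(drop_local)]
    max_round = round_no + 1
    selected = np.zeros(p, bool)
    for f in surviving:
        rank[f] = max_round
        selected[f] = True
    return FeatureScores(list(table.feature_names), rank, "rfe", selected)


def select_from_importance(
    importances,
    threshold_rule="mean",
    feature_names: list[str] | None = None,
) -> FeatureScores:
    """Select features whose importance meets a threshold.

    ``threshold_rule`` is either the string ``"mean"`` (threshold at the
    mean importance — the usual convention for forest importances) or an
    explicit numeric value.
    """
    imp = np.asarray(importances, dtype=float)
    if np.any(imp < 0):
        raise ValueError("importances must be non-negative")
    names = feature_names if feature_names is not None else [
        f"feature_{i}" for i in range(len(imp))
    ]
    if threshold_rule == "mean":
        threshold = float(imp.mean())
    else:
        threshold = float(threshold_rule)
    if np.all(imp == 0):
        warnings.warn("all importances are zero; empty selection", stacklevel=2)
        selected = np.zeros(len(imp), bool)
    else:
        selected = imp >= threshold
        if not selected.any():
            warnings.warn("threshold above maximum importance; empty selection",
                          stacklevel=2)
    return FeatureScores(list(names), imp, "importance_threshold", selected)


_CATEGORY_BOUNDS = (
    (0.6, "high"),       # |c| >  0.6
    (0.4, "moderate"),   # 0.4 < |c| <= 0.6
    (0.2, "low"),        # 0.2 < |c| <= 0.4
    (-1.0, "minimal"),   # |c| <= 0.2
)


def correlation_categorize(correlations) -> np.ndarray:
    """Map correlation coefficients onto clinical strength categories.

    |c| > 0.6 → "high"; 0.4 < |c| ≤ 0.6 → "moderate";
    0.2 < |c| ≤ 0.4 → "low"; |c| ≤ 0.2 → "minimal".
    Upper bounds are closed: exactly 0.6 is moderate, exactly 0.4 is low.
    Signs are ignored; shape is preserved.
    """
    c = np.asarray(correlations, dtype=float)
    if np.any(np.abs(c) > 1):
        bad = c.flat[int(np.argmax(np.abs(c)))]
        raise ValueError(f"correlation {bad} outside [-1, 1]")
    a = np.abs(c)
    out = np.empty(c.shape, dtype=object)
    out[a <= 0.2] = "minimal"
    out[(a > 0.2) & (a <= 0.4)] = "low"
    out[(a > 0.4) & (a <= 0.6)] = "moderate"
    out[a > 0.6] = "high"
    return out


def stump_importance(table: FeatureTable) -> np.ndarray:
    """Decision-stump importance: best single-threshold classification
    accuracy per feature, in excess of the majority-class rate.

    Deterministic and dependency-free; serves as the default ranker for
    :func:`rfe` in self-contained runs.
    """
    y = table.labels
    n = table.n_samples
    base = max(np.mean(y == 0), np.mean(y == 1))
    imp = np.zeros(table.n_features)
    for j in range(table.n_features):
        order = np.argsort(table.features[:, j], kind="stable")
        y_sorted = y[order]
        # accuracy of "predict 1 above cut" over all n+1 cut positions
        ones_below = np.concatenate([[0], np.cumsum(y_sorted == 1)])
        zeros_below = np.concatenate([[0], np.cumsum(y_sorted == 0)])
        correct_up = (zeros_below + (ones_below[-1] - ones_below))
        acc = np.maximum(correct_up, n - correct_up) / n  # either polarity
        imp[j] = acc.max() - base
    return np.maximum(imp, 0.0)
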