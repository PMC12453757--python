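"""Tabular data loading and the preprocessing chain.

The pipeline applied before swarm training is: load a CSV feature table,
drop identifier columns, balance the classes with SMOTE, split into train
and test partitions, and standardize features on training statistics.

:class:`FeatureTable` is the package's universal tabular currency: a dense
float feature matrix, its column names, and a binary {0, 1} label vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "FeatureTable",
    "ScalerParams",
    "load_table",
    "recode_labels",
    "smote_oversample",
    "split_train_test",
    "standardize",
]


@dataclass
class FeatureTable:
    """A named feature matrix with a binary label vector.

    Parameters
    ----------
    features:
        ``(n_samples, n_features)`` float matrix; no missing values allowed.
    feature_names:
        Unique column names, one per feature column.
    labels:
        Integer vector with values in ``{0, 1}``; class 1 is the positive
        (disease) class throughout the package.
    """

    features: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, p = self.features.shape
        if n < 1 or p < 1:
            raise ValueError("feature matrix must have at least one row and one column")
        if len(self.feature_names) != p:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.features)):
            bad = np.argwhere(~np.isfinite(self.features))[0]
            raise ValueError(
                f"missing/non-finite value in column "
                f"{self.feature_names[bad[1]]!r}, row {bad[0]}"
            )
        if self.labels.shape != (n,):
            raise ValueError("labels must be a vector with one entry per row")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1}:
            raise ValueError(
                f"labels must be in {{0, 1}}; found values {sorted(uniq)} "
                "(use recode_labels to map a two-valued column)"
            )
        self.labels = self.labels.astype(int)
        self.feature_names = list(self.feature_names)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[int, int]:
        return {c: int(np.sum(self.labels == c)) for c in (0, 1)}

    def subset(self, rows: np.ndarray) -> "FeatureTable":
        """Row-subset table (copies)."""
        rows = np.asarray(rows)
        return FeatureTable(
            self.features[rows].copy(), list(self.feature_names), self.labels[rows].copy()
        )

    def to_dataframe(self, label_name: str = "status") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[label_name] = self.labels
        return df

    def to_csv(self, path: str | Path, label_name: str = "status") -> None:
        self.to_dataframe(label_name).to_csv(path, index=False)


def load_table(
    path: str | Path,
    target_column: str,
    drop_columns: list[str] | tuple[str, ...] = (),
) -> FeatureTable:
    """Load a CSV into a :class:`FeatureTable`.

    Drops ``drop_columns`` (e.g. a patient ``name`` or an uninformative
    ``DoctorInCharge`` column), coerces remaining columns to float and the
    target to integers in {0, 1}. Row order is preserved.
    """
    df = pd.read_csv(path)
    if target_column not in df.columns:
        raise ValueError(
            f"target column {target_column!r} not found in {path} "
            f"(columns: {list(df.columns)})"
        )
    df = df.drop(columns=[c for c in drop_columns if c in df.columns])
    y = df[target_column]
    uniq = set(pd.unique(y).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(
            f"target column {target_column!r} has values {sorted(uniq, key=str)}; "
            "expected {0, 1} — recode with recode_labels first"
        )
    features = df.drop(columns=[target_column])
    for col in features.columns:
        coerced = pd.to_numeric(features[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0])
            raise ValueError(
                f"non-numeric or missing value in column {col!r} at row {row}"
            )
        features[col] = coerced
    return FeatureTable(
        features.to_numpy(dtype=float),
        [str(c) for c in features.columns],
        y.to_numpy(),
    )


def recode_labels(values, positive_value) -> np.ndarray:
    """Map an arbitrary two-valued label column onto {0, 1}.

    ``positive_value`` becomes 1; the single other value becomes 0.
    """
    values = np.asarray(values)
    uniq = pd.unique(values)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two distinct label values, got {list(uniq)}")
    if positive_value not in uniq:
        raise ValueError(f"positive value {positive_value!r} not present in labels")
    return (values == positive_value).astype(int)


def smote_oversample(
    table: FeatureTable,
    k_neighbors: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
) -> FeatureTable:
    """Balance classes by SMOTE interpolation.

    New minority samples are drawn on the segment between a random minority
    point ``x`` and one of its ``k_neighbors`` nearest minority neighbours
    ``x_nn``: ``x_new = x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``.
    Original rows are preserved verbatim; synthetic rows are appended with
    the minority label. The minority class is raised to
    ``round(target_ratio * majority_count)`` samples.
    """
    counts = table.class_counts()
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("SMOTE requires both classes present")
    minority = 0 if counts[0] < counts[1] else 1
    majority = 1 - minority
    n_min, n_maj = counts[minority], counts[majority]
    target = int(round(target_ratio * n_maj))
    n_new = target - n_min
    if n_new <= 0:
        return table
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority class has {n_min} samples but k_neighbors={k_neighbors}; "
            f"use k_neighbors < {n_min}"
        )
    rng = np.random.default_rng(seed)
    X_min = table.features[table.labels == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    # column 0 of the neighbour index is the point itself
    neighbour_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x = X_min[base]
    x_nn = X_min[neighbour_idx[base, pick]]
    synthetic = x + u[:, None] * (x_nn - x)
    return FeatureTable(
        np.vstack([table.features, synthetic]),
        list(table.feature_names),
        np.concatenate([table.labels, np.full(n_new, minority, dtype=int)]),
    )


def split_train_test(
    table: FeatureTable,
    test_fraction: float,
    seed: int,
    stratified: bool = True,
) -> tuple[FeatureTable, FeatureTable]:
    """Partition rows into train/test parts; deterministic per seed."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    idx = np.arange(table.n_samples)
    strat = table.labels if stratified else None
    try:
        train_idx, test_idx = train_test_split(
            idx, test_size=test_fraction, random_state=seed, stratify=strat
        )
    except ValueError as exc:  # e.g. a class would be emptied
        raise ValueError(f"cannot split: {exc}") from exc
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("split produced an empty partition")
    return table.subset(np.sort(train_idx)), table.subset(np.sort(test_idx))


@dataclass
class ScalerParams:
    """Per-feature standardization parameters fitted on training data.

    Uses the population (divide-by-n) standard deviation convention.
    """

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.sd + self.mean


def standardize(
    train: FeatureTable, test: FeatureTable
) -> tuple[FeatureTable, FeatureTable, ScalerParams]:
    """Z-score both tables with mean/SD fitted on the training table only."""
    if train.feature_names != test.feature_names:
        raise ValueError("train and test feature names differ")
    mean = train.features.mean(axis=0)
    sd = train.features.std(axis=0)  # population SD
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [train.feature_names[i] for i in zero]
        raise ValueError(
            f"zero-variance training feature(s) {names}; variance-filter first"
        )
    params = ScalerParams(mean, sd)
    out_train = FeatureTable(
        params.transform(train.features), list(train.feature_names), train.labels.copy()
    )
    out_test = FeatureTable(
        params.transform(test.features), list(test.feature_names), test.labels.copy()
    )
    return out_train, out_test, params
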