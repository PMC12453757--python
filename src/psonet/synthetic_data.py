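"""Reproducible synthetic tabular datasets for diagnostic-classifier studies.

Two generators emulate the statistical structure of typical Parkinson's
prediction benchmarks without any real data:

* :func:`generate_voice_like` — an imbalanced two-class table of positively
  correlated continuous acoustic features (jitter / shimmer / noise-ratio
  style) whose class-conditional means differ by a configurable shift.
* :func:`generate_clinical_like` — a larger mixed table adding binary
  demographic / medical-history columns drawn as class-dependent Bernoulli
  variables.

Labels are assigned first (exact class counts), features sampled
conditionally on the label from a multivariate normal with block-constant
correlation; selected columns may be exponentiated to obtain the heavy
right skew of jitter-like measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .preprocess import FeatureTable

__all__ = [
    "SyntheticSpec",
    "generate_voice_like",
    "generate_clinical_like",
    "VOICE_FEATURE_NAMES",
    "CLINICAL_FEATURE_NAMES",
]

# Acoustic vocabulary mirroring the classic voice-biomarker feature set:
# fundamental-frequency statistics, jitter and shimmer variants, noise
# ratios and nonlinear dynamical measures.
VOICE_FEATURE_NAMES: tuple[str, ...] = (
    "MDVP:Fo(Hz)", "MDVP:Fhi(Hz)", "MDVP:Flo(Hz)",
    "MDVP:Jitter(%)", "MDVP:Jitter(Abs)", "MDVP:RAP", "MDVP:PPQ",
    "Jitter:DDP", "MDVP:Shimmer", "MDVP:Shimmer(dB)",
    "Shimmer:APQ3", "Shimmer:APQ5", "MDVP:APQ", "Shimmer:DDA",
    "NHR", "HNR", "RPDE", "DFA", "spread1", "spread2", "D2", "PPE",
)

CLINICAL_FEATURE_NAMES: tuple[str, ...] = (
    "Age", "Gender", "Ethnicity", "EducationLevel", "BMI",
    "Smoking", "AlcoholConsumption", "PhysicalActivity", "DietQuality",
    "SleepQuality", "FamilyHistoryParkinsons", "TraumaticBrainInjury",
    "Hypertension", "Diabetes", "Depression", "Stroke",
    "SystolicBP", "DiastolicBP", "CholesterolTotal", "CholesterolLDL",
    "CholesterolHDL", "CholesterolTriglycerides", "UPDRS", "MoCA",
    "FunctionalAssessment", "Tremor", "Rigidity", "Bradykinesia",
    "PosturalInstability", "SpeechProblems", "SleepDisorders", "Constipation",
)


@dataclass
class SyntheticSpec:
    """Distributional recipe for a generated dataset.

    Parameters
    ----------
    n_samples, n_features:
        Table dimensions (label column excluded from ``n_features``).
    class1_fraction:
        Fraction of rows labelled 1; class-1 count is
        ``round(n_samples * class1_fraction)``, exactly.
    mean_shift:
        Per-feature class-1 minus class-0 mean difference, in feature SD
        units. A scalar is broadcast to all continuous features.
    correlation_blocks:
        ``[(feature_index_set, rho), ...]`` — features inside a block share
        a common pairwise correlation ``rho`` in [0, 1).
    noise_sd:
        Standard deviation of every continuous feature.
    binary_feature_indices:
        Columns generated as class-dependent Bernoulli draws instead of
        Gaussians (clinical-style tables only).
    binary_rates:
        ``{feature_index: (rate_class0, rate_class1)}`` Bernoulli success
        probabilities; defaults to (0.3, 0.5) for unlisted binary columns.
    skewed_feature_indices:
        Continuous columns exponentiated after sampling, producing a
        log-normal right skew typical of jitter/shimmer measurements.
    seed:
        Seed for the generator's random stream.
    """

    n_samples: int
    n_features: int
    class1_fraction: float = 0.5
    mean_shift: float | list[float] = 0.0
    correlation_blocks: list[tuple[frozenset, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    binary_feature_indices: frozenset = field(default_factory=frozenset)
    binary_rates: dict[int, tuple[float, float]] = field(default_factory=dict)
    skewed_feature_indices: frozenset = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_features < 1:
            raise ValueError("n_samples and n_features must be positive")
        if not 0.0 < self.class1_fraction < 1.0:
            raise ValueError("class1_fraction must lie strictly inside (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.binary_feature_indices = frozenset(int(i) for i in self.binary_feature_indices)
        self.skewed_feature_indices = frozenset(int(i) for i in self.skewed_feature_indices)
        self.correlation_blocks = [
            (frozenset(int(i) for i in idx), float(rho))
            for idx, rho in self.correlation_blocks
        ]
        all_idx = self.binary_feature_indices | self.skewed_feature_indices
        for idx, _ in self.correlation_blocks:
            all_idx |= idx
        if all_idx and (min(all_idx) < 0 or max(all_idx) >= self.n_features):
            raise ValueError("feature index out of range")
        seen: set[int] = set()
        for idx, rho in self.correlation_blocks:
            if idx & seen:
                raise ValueError("correlation blocks must be disjoint")
            seen |= idx
            if not 0.0 <= rho < 1.0:
                raise ValueError(
                    f"block {sorted(idx)}: correlation {rho} outside [0, 1) "
                    "gives a non-positive-definite covariance"
                )
            if idx & self.binary_feature_indices:
                raise ValueError("correlation blocks may not include binary features")
        for i, (p0, p1) in self.binary_rates.items():
            if i not in self.binary_feature_indices:
                raise ValueError(f"binary rate given for non-binary feature {i}")
            if not (0.0 < p0 < 1.0 and 0.0 < p1 < 1.0):
                raise ValueError(
                    f"Bernoulli probability for feature {i} outside (0, 1)"
                )
        shift = np.broadcast_to(
            np.atleast_1d(np.asarray(self.mean_shift, dtype=float)), (self.n_features,)
        ) if np.ndim(self.mean_shift) == 0 else np.asarray(self.mean_shift, dtype=float)
        if shift.shape != (self.n_features,):
            raise ValueError("mean_shift length must equal n_features")
        self._shift = shift

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        d = asdict(self)
        d["correlation_blocks"] = [
            [sorted(idx), rho] for idx, rho in self.correlation_blocks
        ]
        d["binary_feature_indices"] = sorted(self.binary_feature_indices)
        d["skewed_feature_indices"] = sorted(self.skewed_feature_indices)
        d["binary_rates"] = {str(k): list(v) for k, v in self.binary_rates.items()}
        d.pop("_shift", None)
        if not np.ndim(self.mean_shift) == 0:
            d["mean_shift"] = list(np.asarray(self.mean_shift, dtype=float))
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        d["correlation_blocks"] = [
            (frozenset(idx), rho) for idx, rho in d.get("correlation_blocks", [])
        ]
        d["binary_feature_indices"] = frozenset(d.get("binary_feature_indices", []))
        d["skewed_feature_indices"] = frozenset(d.get("skewed_feature_indices", []))
        d["binary_rates"] = {
            int(k): tuple(v) for k, v in d.get("binary_rates", {}).items()
        }
        return cls(**d)


def _correlation_matrix(spec: SyntheticSpec, continuous_idx: np.ndarray) -> np.ndarray:
    p = len(continuous_idx)
    pos = {int(f): i for i, f in enumerate(continuous_idx)}
    R = np.eye(p)
    for idx, rho in spec.correlation_blocks:
        members = [pos[i] for i in sorted(idx)]
        for a in members:
            for b in members:
                if a != b:
                    R[a, b] = rho
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - blocked by validation
        raise ValueError(
            f"correlation blocks produce a non-positive-definite covariance: "
            f"{spec.correlation_blocks}"
        ) from exc
    return R


def _feature_names(spec: SyntheticSpec, vocabulary: tuple[str, ...]) -> list[str]:
    names = list(vocabulary[: spec.n_features])
    while len(names) < spec.n_features:
        names.append(f"feature_{len(names) + 1}")
    return names


def _generate(spec: SyntheticSpec, vocabulary: tuple[str, ...]) -> FeatureTable:
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    n1 = int(round(n * spec.class1_fraction))
    if n1 == 0 or n1 == n:
        raise ValueError("class1_fraction leaves a class empty at this n_samples")
    labels = np.zeros(n, dtype=int)
    labels[:n1] = 1  # labels first, features conditional on label

    binary_idx = np.array(sorted(spec.binary_feature_indices), dtype=int)
    continuous_idx = np.array(
        [i for i in range(p) if i not in spec.binary_feature_indices], dtype=int
    )
    X = np.empty((n, p))

    if continuous_idx.size:
        R = _correlation_matrix(spec, continuous_idx)
        cov = (spec.noise_sd**2) * R
        chol = np.linalg.cholesky(cov)
        Z = rng.standard_normal((n, continuous_idx.size)) @ chol.T
        shift = spec._shift[continuous_idx] * spec.noise_sd
        Z[labels == 1] += shift
        X[:, continuous_idx] = Z

    for i in binary_idx:
        p0, p1 = spec.binary_rates.get(int(i), (0.3, 0.5))
        rates = np.where(labels == 1, p1, p0)
        X[:, i] = (rng.uniform(size=n) < rates).astype(float)

    for i in sorted(spec.skewed_feature_indices):
        X[:, i] = np.exp(X[:, i])

    # shuffle rows so class blocks are interleaved (deterministic per seed)
    order = rng.permutation(n)
    return FeatureTable(X[order], _feature_names(spec, vocabulary), labels[order])


def generate_voice_like(spec: SyntheticSpec) -> FeatureTable:
    """Generate an acoustic-style continuous feature table.

    All columns are continuous (``binary_feature_indices`` must be empty);
    names are drawn from the jitter/shimmer/HNR vocabulary. The label
    column is conventionally written as ``status``.
    """
    if spec.binary_feature_indices:
        raise ValueError("voice-like tables have no binary features")
    return _generate(spec, VOICE_FEATURE_NAMES)


def generate_clinical_like(spec: SyntheticSpec) -> FeatureTable:
    """Generate a mixed demographic/clinical-style table.

    Columns listed in ``binary_feature_indices`` are class-dependent
    Bernoulli draws in {0, 1}; the rest behave as in
    :func:`generate_voice_like`. The label column is conventionally
    written as ``Diagnosis``.
    """
    return _generate(spec, CLINICAL_FEATURE_NAMES)


def write_csv(table: FeatureTable, path: str | Path, label_name: str) -> None:
    """Write a generated table with the study-style label column name."""
    table.to_csv(path, label_name=label_name)
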