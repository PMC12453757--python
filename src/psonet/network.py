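"""Single-hidden-layer feed-forward classifier trained by swarm search.

The network is deliberately simple — ReLU hidden layer, softmax output,
two output nodes for binary classification — because its parameters are
optimized by a particle swarm rather than by backpropagation: every
particle position is a flat vector of all weights and biases, decoded by
the codec here into layer matrices for the forward pass.

The swarm's fitness is the mean negative log-likelihood on training data
plus an L2 penalty on the weights (biases excluded, no 1/2 factor).
Inverted dropout on the hidden layer is available for stochastic fitness
evaluation: masked units are zeroed and survivors rescaled by
``1 / (1 - dropout_rate)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkSpec",
    "ParameterVector",
    "param_dim",
    "encode_params",
    "decode_params",
    "forward",
    "forward_batch",
    "fitness_loss",
    "fitness_loss_batch",
    "predict",
]

_PROB_FLOOR = 1e-12  # keeps -log finite under the extreme weights PSO explores


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture constants of the classifier.

    ``n_hidden=256``, ``dropout_rate=0.5`` and ``l2_lambda=0.01`` are the
    study defaults; ``n_output`` is fixed at 2 (binary softmax output).
    """

    n_input: int
    n_hidden: int = 256
    n_output: int = 2
    dropout_rate: float = 0.5
    l2_lambda: float = 0.01

    def __post_init__(self) -> None:
        if self.n_input < 1 or self.n_hidden < 1:
            raise ValueError("layer sizes must be positive")
        if self.n_output != 2:
            raise ValueError("binary classifier: n_output must be 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")

    @property
    def param_dim(self) -> int:
        """Total number of weights and biases (the PSO search dimension)."""
        return (
            self.n_input * self.n_hidden
            + self.n_hidden
            + self.n_hidden * self.n_output
            + self.n_output
        )


@dataclass
class ParameterVector:
    """Flat weight/bias vector — the position a particle occupies."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


def param_dim(spec: NetworkSpec) -> int:
    return spec.param_dim


def _as_array(params) -> np.ndarray:
    return np.asarray(getattr(params, "values", params), dtype=float)


def decode_params(params, spec: NetworkSpec):
    """Split a flat vector into ``(W1, b1, W2, b2)``.

    Layout: input-to-hidden weights (row-major, n_input x n_hidden), hidden
    biases, hidden-to-output weights, output biases.
    """
    v = _as_array(params).ravel()
    D = spec.param_dim
    if v.shape[0] != D:
        raise ValueError(f"parameter vector has length {v.shape[0]}, expected D={D}")
    p, h, o = spec.n_input, spec.n_hidden, spec.n_output
    i = 0
    W1 = v[i : i + p * h].reshape(p, h); i += p * h
    b1 = v[i : i + h]; i += h
    W2 = v[i : i + h * o].reshape(h, o); i += h * o
    b2 = v[i : i + o]
    return W1, b1, W2, b2


def encode_params(W1, b1, W2, b2) -> np.ndarray:
    """Inverse of :func:`decode_params`; round-trip is exact."""
    return np.concatenate(
        [np.ravel(W1), np.ravel(b1), np.ravel(W2), np.ravel(b2)]
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward_batch(
    positions: np.ndarray,
    X: np.ndarray,
    spec: NetworkSpec,
    dropout_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Forward pass for a whole batch of parameter vectors at once.

    ``positions`` is ``(k, D)``; the result is ``(k, n, 2)`` of class
    probabilities. A single dropout mask, when given, applies to every
    particle in the batch. Batching lets one swarm step cost two large
    matrix products instead of ``k`` small ones.
    """
    P = np.atleast_2d(np.asarray(positions, dtype=float))
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.n_input:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"expected n_input={spec.n_input}"
        )
    D = spec.param_dim
    if P.shape[1] != D:
        raise ValueError(f"positions have dimension {P.shape[1]}, expected D={D}")
    k = P.shape[0]
    p, h, o = spec.n_input, spec.n_hidden, spec.n_output
    W1 = P[:, : p * h].reshape(k, p, h)
    b1 = P[:, p * h : p * h + h]
    W2 = P[:, p * h + h : p * h + h + h * o].reshape(k, h, o)
    b2 = P[:, p * h + h + h * o :]
    # One GEMM for the hidden layer across all particles, kept in (n, k, h)
    # layout so the bias/ReLU pass runs over contiguous memory.
    H = (X @ W1.transpose(1, 0, 2).reshape(p, k * h)).reshape(-1, k, h)
    np.maximum(H + b1[None, :, :], 0.0, out=H)
    if dropout_mask is not None:
        mask = np.asarray(dropout_mask, dtype=float).ravel()
        if mask.shape[0] != h:
            raise ValueError(f"dropout mask has length {mask.shape[0]}, expected {h}")
        H *= mask / (1.0 - spec.dropout_rate)
    Z = np.matmul(H.transpose(1, 0, 2), W2) + b2[:, None, :]
    return _softmax(Z)


def forward(
    params,
    X: np.ndarray,
    spec: NetworkSpec,
    dropout_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Class-probability matrix ``(n, 2)``; rows sum to 1."""
    return forward_batch(_as_array(params)[None, :], X, spec, dropout_mask)[0]


def fitness_loss_batch(
    positions: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    spec: NetworkSpec,
    dropout_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean NLL + L2 penalty for every parameter vector in the batch."""
    P = np.atleast_2d(np.asarray(positions, dtype=float))
    y = np.asarray(y, dtype=int)
    probs = forward_batch(P, X, spec, dropout_mask)
    p_true = np.clip(probs[:, np.arange(y.shape[0]), y], _PROB_FLOOR, None)
    nll = -np.log(p_true).mean(axis=1)
    if spec.l2_lambda > 0:
        p, h, o = spec.n_input, spec.n_hidden, spec.n_output
        w1 = P[:, : p * h]
        w2 = P[:, p * h + h : p * h + h + h * o]
        penalty = spec.l2_lambda * ((w1**2).sum(axis=1) + (w2**2).sum(axis=1))
    else:
        penalty = 0.0
    return nll + penalty


def fitness_loss(
    params,
    X: np.ndarray,
    y: np.ndarray,
    spec: NetworkSpec,
    dropout_mask: np.ndarray | None = None,
) -> float:
    """Negative log-likelihood with L2 weight penalty (biases excluded)."""
    return float(fitness_loss_batch(_as_array(params)[None, :], X, y, spec, dropout_mask)[0])


def predict(params, X: np.ndarray, spec: NetworkSpec):
    """Hard labels and class-1 scores; dropout is never applied here.

    An exact 0.5/0.5 tie resolves to class 1 (the disease class) — the
    clinically conservative choice favouring sensitivity.
    """
    probs = forward(params, X, spec)
    scores = probs[:, 1]
    labels = (scores >= probs[:, 0]).astype(int)
    return labels, scores
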