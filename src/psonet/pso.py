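"""Particle swarm optimization and the full swarm-training loop.

A swarm of candidate weight vectors explores the network's parameter
space. Each particle keeps its personal best position (pbest); the swarm
tracks the global best (gbest). Per step, every particle's fitness is
evaluated at its current position, bests are updated, and only then do
velocities and positions move (evaluation-before-move ordering):

    v' = w*v + c1*r1∘(pbest - x) + c2*r2∘(gbest - x)      (clamped to ±v_max)
    x' = x + v'

with r1, r2 fresh per-dimension Uniform(0,1) draws. The inertia weight w
is either constant or decays linearly from ``w_start`` to ``w_end``.

:func:`train` wraps the swarm in an epoch loop with early stopping on a
monitored loss: each epoch runs ``iterations_per_epoch`` swarm steps with
the training-set loss as fitness, then evaluates the gbest on a monitor
table; training stops when the monitored loss fails to improve by more
than ``tol`` for ``patience`` consecutive epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import network
from .network import NetworkSpec, ParameterVector
from .preprocess import FeatureTable

__all__ = [
    "SwarmConfig",
    "Particle",
    "Swarm",
    "TrainResult",
    "init_swarm",
    "inertia_at",
    "update_velocity",
    "update_position",
    "step_swarm",
    "train",
]

logger = logging.getLogger(__name__)


@dataclass
class SwarmConfig:
    """All search hyperparameters of the swarm optimizer.

    Defaults follow the study configuration: 100 particles, cognitive and
    social coefficients c1=0.5 / c2=0.3, inertia fixed at 0.9 (a linear
    0.9→0.4 decay is available as ``inertia_mode="linear_decay"``),
    positions initialized in [0, 1], up to 1000 epochs with early-stopping
    patience 10.
    """

    swarm_size: int = 100
    c1: float = 0.5
    c2: float = 0.3
    inertia_mode: str = "constant"  # or "linear_decay"
    w_start: float = 0.9
    w_end: float = 0.4
    v_max: float = 1.0
    init_low: float = 0.0
    init_high: float = 1.0
    iterations_per_epoch: int = 10
    max_epochs: int = 1000
    patience: int = 10
    tol: float = 1e-6
    dropout_in_fitness: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be at least 2")
        if self.inertia_mode not in ("constant", "linear_decay"):
            raise ValueError(f"unknown inertia_mode {self.inertia_mode!r}")
        if self.w_end > self.w_start:
            raise ValueError("w_end must not exceed w_start")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.init_high <= self.init_low:
            raise ValueError("init_high must exceed init_low")
        if self.iterations_per_epoch < 1 or self.max_epochs < 1:
            raise ValueError("iteration counts must be positive")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float = np.inf


@dataclass
class Swarm:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    rng: np.random.Generator


@dataclass
class TrainResult:
    """Outcome of a swarm-training run.

    ``history`` holds one ``(train_fitness, monitored_loss)`` pair per
    completed epoch; with deterministic fitness the train-fitness sequence
    is non-increasing (gbest only ever improves).
    """

    best_params: ParameterVector
    history: list[tuple[float, float]]
    stopped_epoch: int
    stop_reason: str  # "max_epochs" | "early_stop"


def init_swarm(config: SwarmConfig, dimension: int) -> Swarm:
    """Seeded random swarm: positions ~ U(init_low, init_high),
    velocities ~ U(-v_max, v_max); bests unset until first evaluation."""
    if dimension < 1:
        raise ValueError("dimension must be positive")
    rng = np.random.default_rng(config.seed)
    particles = []
    for _ in range(config.swarm_size):
        pos = rng.uniform(config.init_low, config.init_high, size=dimension)
        vel = rng.uniform(-config.v_max, config.v_max, size=dimension)
        particles.append(Particle(pos, vel, pos.copy(), np.inf))
    return Swarm(particles, particles[0].position.copy(), np.inf, rng)


def inertia_at(epoch: int, config: SwarmConfig) -> float:
    """Inertia weight at a given (0-based) iteration of the schedule.

    Constant mode always returns ``w_start``; linear mode interpolates
    ``w_start - (w_start - w_end) * epoch / max_epochs``, hitting exactly
    ``w_start`` at iteration 0 and ``w_end`` at the final iteration.
    """
    if not 0 <= epoch <= config.max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.max_epochs}]")
    if config.inertia_mode == "constant":
        return config.w_start
    return config.w_start - (config.w_start - config.w_end) * epoch / config.max_epochs


def update_velocity(
    particle: Particle,
    gbest: np.ndarray,
    w: float,
    config: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """New velocity, component-clamped to [-v_max, +v_max]."""
    d = particle.position.shape[0]
    if gbest.shape[0] != d:
        raise ValueError("gbest dimension mismatch")
    r1 = rng.uniform(size=d)
    r2 = rng.uniform(size=d)
    v = (
        w * particle.velocity
        + config.c1 * r1 * (particle.pbest_position - particle.position)
        + config.c2 * r2 * (gbest - particle.position)
    )
    return np.clip(v, -config.v_max, config.v_max)


def update_position(particle: Particle, new_velocity: np.ndarray) -> np.ndarray:
    """x' = x + v'. Positions are unclamped: weights must be free to leave
    the [0, 1] initialization box to fit standardized features."""
    if new_velocity.shape != particle.position.shape:
        raise ValueError("velocity dimension mismatch")
    return particle.position + new_velocity


def _evaluate_fitness(fitness, positions: np.ndarray) -> np.ndarray:
    batch = getattr(fitness, "evaluate_batch", None)
    if batch is not None:
        return np.asarray(batch(positions), dtype=float)
    return np.array([float(fitness(p)) for p in positions])


def step_swarm(swarm: Swarm, fitness, w: float, config: SwarmConfig) -> Swarm:
    """One PSO iteration: evaluate, update bests, then move.

    ``fitness`` maps a position to a scalar to minimize; an object with an
    ``evaluate_batch(positions) -> vector`` method is evaluated for the
    whole swarm at once.
    """
    positions = np.stack([p.position for p in swarm.particles])
    values = _evaluate_fitness(fitness, positions)
    for i, (particle, f) in enumerate(zip(swarm.particles, values)):
        if not np.isfinite(f):
            raise ValueError(f"non-finite fitness {f} for particle {i}")
        if f < particle.pbest_fitness:
            particle.pbest_fitness = float(f)
            particle.pbest_position = particle.position.copy()
    best = min(swarm.particles, key=lambda p: p.pbest_fitness)
    if best.pbest_fitness < swarm.gbest_fitness:
        swarm.gbest_fitness = best.pbest_fitness
        swarm.gbest_position = best.pbest_position.copy()
    for particle in swarm.particles:
        v = update_velocity(particle, swarm.gbest_position, w, config, swarm.rng)
        particle.position = update_position(particle, v)
        particle.velocity = v
    return swarm


class _NetworkFitness:
    """Training-set loss as swarm fitness, batch-evaluated.

    With ``dropout_in_fitness`` a fresh hidden-unit mask is drawn per
    evaluation (shared across the swarm within a step), making the fitness
    stochastic; off by default so gbest is monotone.
    """

    def __init__(self, X, y, spec: NetworkSpec, dropout: bool, rng: np.random.Generator):
        self.X, self.y, self.spec = X, y, spec
        self.dropout = dropout and spec.dropout_rate > 0
        self.rng = rng

    def _mask(self):
        if not self.dropout:
            return None
        return (self.rng.uniform(size=self.spec.n_hidden) >= self.spec.dropout_rate)

    def evaluate_batch(self, positions: np.ndarray) -> np.ndarray:
        return network.fitness_loss_batch(positions, self.X, self.y, self.spec, self._mask())

    def __call__(self, position: np.ndarray) -> float:
        return float(self.evaluate_batch(position[None, :])[0])


def train(
    train_table: FeatureTable,
    monitor_table: FeatureTable,
    spec: NetworkSpec,
    config: SwarmConfig,
) -> TrainResult:
    """Optimize the network on ``train_table``, early-stopping on
    ``monitor_table`` loss (same NLL+L2 formula, no dropout)."""
    if monitor_table.n_samples == 0:
        raise ValueError("monitor table is empty")
    if train_table.n_features != spec.n_input or monitor_table.n_features != spec.n_input:
        raise ValueError("table width does not match spec.n_input")
    D = spec.param_dim
    swarm = init_swarm(config, D)
    fitness = _NetworkFitness(
        train_table.features, train_table.labels, spec,
        config.dropout_in_fitness, swarm.rng,
    )
    history: list[tuple[float, float]] = []
    best_monitor = np.inf
    stall = 0
    stop_reason = "max_epochs"
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        w = inertia_at(epoch - 1, config)
        for _ in range(config.iterations_per_epoch):
            step_swarm(swarm, fitness, w, config)
        monitored = network.fitness_loss(
            swarm.gbest_position, monitor_table.features, monitor_table.labels, spec
        )
        if not np.isfinite(monitored):
            raise ValueError("non-finite monitored loss")
        history.append((float(swarm.gbest_fitness), float(monitored)))
        logger.info(
            "epoch %d: gbest fitness %.6f, monitored loss %.6f",
            epoch, swarm.gbest_fitness, monitored,
        )
        if best_monitor - monitored > config.tol:
            best_monitor = monitored
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                stop_reason = "early_stop"
                break
    return TrainResult(
        ParameterVector(swarm.gbest_position.copy()), history, epoch, stop_reason
    )
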