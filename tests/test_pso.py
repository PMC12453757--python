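"""Swarm optimizer mechanics: initialization, inertia schedule, the
velocity/position update equations, best-tracking, convergence, and the
epoch loop with early stopping."""

import numpy as np
import pytest

from psonet.network import NetworkSpec
from psonet.preprocess import FeatureTable
from psonet.pso import (
    Particle,
    SwarmConfig,
    inertia_at,
    init_swarm,
    step_swarm,
    train,
    update_position,
    update_velocity,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class PinnedRng:
    """Stub RNG returning queued uniform draws, for hand-checked updates."""

    def __init__(self, draws):
        self.draws = list(draws)

    def uniform(self, low=0.0, high=1.0, size=None):
        return np.asarray(self.draws.pop(0), dtype=float)


# -- init -------------------------------------------------------------------


def test_init_swarm_deterministic():
    cfg = SwarmConfig(swarm_size=10, seed=3)
    a, b = init_swarm(cfg, 8), init_swarm(cfg, 8)
    for pa, pb in zip(a.particles, b.particles):
        np.testing.assert_array_equal(pa.position, pb.position)
        np.testing.assert_array_equal(pa.velocity, pb.velocity)


def test_init_positions_within_unit_range():
    cfg = SwarmConfig(swarm_size=20, seed=0)
    swarm = init_swarm(cfg, 50)
    for p in swarm.particles:
        assert np.all((p.position >= 0.0) & (p.position <= 1.0))
        assert np.all(np.abs(p.velocity) <= cfg.v_max)


def test_init_allocates_full_swarm():
    cfg = SwarmConfig(swarm_size=100, seed=0)
    swarm = init_swarm(cfg, 6402)
    assert len(swarm.particles) == 100
    assert all(p.position.shape == (6402,) for p in swarm.particles)


# -- inertia schedule -------------------------------------------------------


def test_inertia_linear_decay_endpoints_and_midpoint():
    cfg = SwarmConfig(inertia_mode="linear_decay", max_epochs=1000)
    assert inertia_at(0, cfg) == 0.9
    assert inertia_at(1000, cfg) == 0.4
    assert inertia_at(500, cfg) == pytest.approx(0.65)


def test_inertia_constant_mode():
    cfg = SwarmConfig(inertia_mode="constant", max_epochs=100)
    assert inertia_at(0, cfg) == inertia_at(100, cfg) == 0.9


def test_inertia_epoch_out_of_range():
    cfg = SwarmConfig(max_epochs=10)
    with pytest.raises(ValueError):
        inertia_at(11, cfg)


# -- velocity / position updates --------------------------------------------


def test_velocity_fixed_point_at_consensus():
    cfg = SwarmConfig(swarm_size=2, v_max=10.0)
    x = np.array([1.0, -2.0])
    particle = Particle(x.copy(), np.zeros(2), x.copy(), 0.0)
    v = update_velocity(particle, x.copy(), 0.9, cfg, np.random.default_rng(0))
    np.testing.assert_array_equal(v, 0.0)


def test_velocity_hand_arithmetic_with_pinned_draws():
    """1-D: 0.9*1 + 0.5*0.5*2 + 0.3*1*4 = 2.6 (before clamping)."""
    cfg = SwarmConfig(swarm_size=2, c1=0.5, c2=0.3, v_max=10.0)
    particle = Particle(np.array([1.0]), np.array([1.0]), np.array([3.0]), 0.0)
    gbest = np.array([5.0])
    rng = PinnedRng([[0.5], [1.0]])
    v = update_velocity(particle, gbest, 0.9, cfg, rng)
    assert v[0] == pytest.approx(2.6, abs=1e-12)


def test_velocity_clamped_to_v_max():
    cfg = SwarmConfig(swarm_size=2, c1=0.5, c2=0.3, v_max=1.0)
    particle = Particle(np.array([1.0]), np.array([1.0]), np.array([3.0]), 0.0)
    v = update_velocity(particle, np.array([5.0]), 0.9, cfg, PinnedRng([[0.5], [1.0]]))
    assert v[0] == 1.0  # 2.6 clamped


def test_position_update_is_addition():
    particle = Particle(np.array([1.0]), np.array([0.0]), np.array([1.0]), 0.0)
    assert update_position(particle, np.array([2.6]))[0] == pytest.approx(3.6)
    np.testing.assert_array_equal(
        update_position(particle, np.array([0.0])), particle.position
    )


def test_vectorized_update_equals_component_loop():
    cfg = SwarmConfig(swarm_size=2, c1=0.5, c2=0.3, v_max=2.0)
    d = 7
    rng_state = np.random.default_rng(9)
    x = rng_state.standard_normal(d)
    vel = rng_state.standard_normal(d)
    pbest = rng_state.standard_normal(d)
    gbest = rng_state.standard_normal(d)
    r1 = rng_state.uniform(size=d)
    r2 = rng_state.uniform(size=d)
    particle = Particle(x.copy(), vel.copy(), pbest.copy(), 0.0)
    v = update_velocity(particle, gbest, 0.7, cfg, PinnedRng([r1, r2]))
    for i in range(d):
        expected = 0.7 * vel[i] + 0.5 * r1[i] * (pbest[i] - x[i]) + 0.3 * r2[i] * (gbest[i] - x[i])
        expected = min(max(expected, -2.0), 2.0)
        assert v[i] == pytest.approx(expected, abs=1e-12)


# -- step_swarm -------------------------------------------------------------


def test_gbest_monotone_under_deterministic_fitness():
    cfg = SwarmConfig(swarm_size=8, seed=1, v_max=0.5)
    swarm = init_swarm(cfg, 4)
    best_so_far = np.inf
    for _ in range(50):
        step_swarm(swarm, sphere, 0.9, cfg)
        assert swarm.gbest_fitness <= best_so_far + 1e-15
        best_so_far = swarm.gbest_fitness
    assert swarm.gbest_fitness == min(p.pbest_fitness for p in swarm.particles)


def test_particle_at_optimum_remains_gbest():
    cfg = SwarmConfig(swarm_size=2, seed=0, c1=0.0, c2=0.0, w_start=0.5, w_end=0.4)
    swarm = init_swarm(cfg, 3)
    swarm.particles[0].position = np.zeros(3)
    swarm.particles[0].velocity = np.zeros(3)
    step_swarm(swarm, sphere, 0.5, cfg)
    assert swarm.gbest_fitness == 0.0
    for _ in range(5):
        step_swarm(swarm, sphere, 0.5, cfg)
    assert swarm.gbest_fitness == 0.0


def test_five_particle_sphere_improves_hundredfold():
    cfg = SwarmConfig(
        swarm_size=5, seed=3, inertia_mode="linear_decay", max_epochs=200
    )
    swarm = init_swarm(cfg, 5)
    step_swarm(swarm, sphere, inertia_at(0, cfg), cfg)
    initial = swarm.gbest_fitness
    for t in range(1, 200):
        step_swarm(swarm, sphere, inertia_at(t, cfg), cfg)
    assert swarm.gbest_fitness < initial / 100


def test_velocity_decay_geometric_without_attraction():
    """c1 = c2 = 0 and w < 1: velocity norm decays exactly as w^t."""
    cfg = SwarmConfig(swarm_size=3, c1=0.0, c2=0.0, seed=2, w_start=0.8, w_end=0.4)
    swarm = init_swarm(cfg, 6)
    expected = [p.velocity.copy() for p in swarm.particles]
    for _ in range(20):
        step_swarm(swarm, sphere, 0.8, cfg)
        for p, e in zip(swarm.particles, expected):
            e *= 0.8
            np.testing.assert_array_equal(p.velocity, e)


def test_non_finite_fitness_names_particle():
    cfg = SwarmConfig(swarm_size=3, seed=0)
    swarm = init_swarm(cfg, 2)
    with pytest.raises(ValueError, match="particle"):
        step_swarm(swarm, lambda x: np.nan, 0.9, cfg)


# -- train loop -------------------------------------------------------------


def _tiny_tables(rng, n=60, p=3, shift=3.0):
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, p))
    X[y == 1] += shift
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    table = FeatureTable(X, [f"f{i}" for i in range(p)], y)
    return table


def test_early_stopping_with_frozen_fitness(rng, monkeypatch):
    """If the monitored loss can never improve, patience=1 stops the loop
    after the second epoch."""
    import psonet.pso as pso_mod

    monkeypatch.setattr(
        pso_mod.network, "fitness_loss",
        lambda *a, **k: 1.0,
    )
    table = _tiny_tables(rng)
    cfg = SwarmConfig(swarm_size=4, iterations_per_epoch=1, max_epochs=50,
                      patience=1, seed=0)
    result = train(table, table, NetworkSpec(3, n_hidden=2), cfg)
    assert result.stopped_epoch == 2
    assert result.stop_reason == "early_stop"
    assert len(result.history) == 2


def test_train_reaches_high_accuracy_on_separable_data(rng):
    from psonet.network import predict

    table = _tiny_tables(rng, n=120, p=3, shift=3.0)
    spec = NetworkSpec(3, n_hidden=8, dropout_rate=0.0, l2_lambda=0.0)
    cfg = SwarmConfig(swarm_size=20, iterations_per_epoch=5, max_epochs=30,
                      patience=5, seed=1)
    result = train(table, table, spec, cfg)
    labels, _ = predict(result.best_params, table.features, spec)
    assert np.mean(labels == table.labels) >= 0.95


def test_train_history_monotone_and_reproducible(rng):
    table = _tiny_tables(rng)
    spec = NetworkSpec(3, n_hidden=4)
    cfg = SwarmConfig(swarm_size=6, iterations_per_epoch=2, max_epochs=10,
                      patience=3, seed=5)
    a = train(table, table, spec, cfg)
    b = train(table, table, spec, cfg)
    fitness_a = [h[0] for h in a.history]
    assert all(x >= y - 1e-15 for x, y in zip(fitness_a, fitness_a[1:]))
    np.testing.assert_array_equal(a.best_params.values, b.best_params.values)
    assert a.history == b.history
    assert a.stopped_epoch == b.stopped_epoch


def test_train_rejects_mismatched_width(rng):
    table = _tiny_tables(rng)
    with pytest.raises(ValueError, match="n_input"):
        train(table, table, NetworkSpec(5, n_hidden=2), SwarmConfig(swarm_size=2))


def test_config_validation():
    with pytest.raises(ValueError):
        SwarmConfig(swarm_size=1)
    with pytest.raises(ValueError):
        SwarmConfig(w_start=0.4, w_end=0.9)
    with pytest.raises(ValueError):
        SwarmConfig(v_max=0.0)
    with pytest.raises(ValueError):
        SwarmConfig(patience=0)
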