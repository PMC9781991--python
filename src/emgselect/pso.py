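"""Binary particle swarm optimization of feature masks.

Each particle holds a binary position X (the mask), a real velocity v, and
its personal best; the swarm tracks the global best.  Velocities follow

    v ← w·v + c1·r1·(pbest − X) + c2·r2·(gbest − X)

with r1, r2 fresh uniform vectors per dimension per update, clamped to
±v_clamp.  A sigmoid S(v) = 1/(1 + e^{−v}) converts each velocity component
to a bit probability, and the new bit is 1 iff S(v) > r3 for a fresh
uniform r3.  Fitness is the same cached CV-error landscape as the GA, so
both selectors optimize an identical objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import SvmSpec
from .errors import ParameterError, ShapeError
from .features import FeatureMatrix
from .ga import MaskFitness, SelectionRun


@dataclass(frozen=True)
class PsoConfig:
    """Swarm settings; defaults follow common binary-PSO practice
    (w = 0.9, c1 = c2 = 2, velocities clamped at ±6 where the sigmoid is
    within 0.25% of saturation)."""

    n_genes: int
    n_particles: int = 10
    w: float = 0.9
    c1: float = 2.0
    c2: float = 2.0
    max_iterations: int = 100
    v_clamp: float = 6.0
    target_error: float | None = None
    seed: int = 0
    cv_k: int = 10
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.n_particles < 1:
            raise ParameterError("n_particles must be >= 1")
        if self.w < 0 or self.c1 < 0 or self.c2 < 0:
            raise ParameterError("w, c1, c2 must be non-negative")
        if self.v_clamp <= 0:
            raise ParameterError("v_clamp must be positive")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")


@dataclass
class Particle:
    X: np.ndarray        # binary position
    v: np.ndarray        # real velocity
    pbest: np.ndarray
    pbest_fitness: float


def update_velocity(
    p: Particle,
    gbest: np.ndarray,
    cfg: PsoConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One velocity update with fresh per-dimension r1, r2; clamped."""
    r1 = rng.random(p.X.size)
    r2 = rng.random(p.X.size)
    v = (
        cfg.w * p.v
        + cfg.c1 * r1 * (p.pbest - p.X)
        + cfg.c2 * r2 * (gbest - p.X)
    )
    return np.clip(v, -cfg.v_clamp, cfg.v_clamp)


def transfer(v: np.ndarray | float) -> np.ndarray | float:
    """Sigmoid transfer S(v) = 1 / (1 + e^{−v}) mapping velocity to bit
    probability; S(0) = 0.5, strictly increasing."""
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))


def update_position(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Each bit set to 1 iff S(v) > r3 for a fresh uniform r3."""
    r3 = rng.random(np.asarray(v).shape)
    return (transfer(v) > r3).astype(np.int8)


def run_pso(m: FeatureMatrix, svm: SvmSpec, cfg: PsoConfig) -> SelectionRun:
    """Minimize the CV error over feature masks with binary PSO."""
    if cfg.n_genes != m.values.shape[1]:
        raise ShapeError(
            f"n_genes={cfg.n_genes} but the matrix has {m.values.shape[1]} columns"
        )
    fitness = MaskFitness(m, svm, k=cfg.cv_k, seed=cfg.cv_seed)
    rng = np.random.default_rng(cfg.seed)

    particles: list[Particle] = []
    for _ in range(cfg.n_particles):
        x = rng.integers(0, 2, size=cfg.n_genes, dtype=np.int8)
        particles.append(
            Particle(X=x, v=np.zeros(cfg.n_genes), pbest=x.copy(),
                     pbest_fitness=fitness(x))
        )
    g_idx = int(np.argmin([p.pbest_fitness for p in particles]))
    gbest = particles[g_idx].pbest.copy()
    gbest_fitness = particles[g_idx].pbest_fitness

    history: list[float] = []
    mean_history: list[float] = []
    n_selected: list[int] = []

    for _ in range(cfg.max_iterations):
        for p in particles:
            p.v = update_velocity(p, gbest, cfg, rng)
            p.X = update_position(p.v, rng)
            f = fitness(p.X)
            if f < p.pbest_fitness:
                p.pbest = p.X.copy()
                p.pbest_fitness = f
            if f < gbest_fitness:
                gbest = p.X.copy()
                gbest_fitness = f
        history.append(gbest_fitness)
        mean_history.append(float(np.mean([p.pbest_fitness for p in particles])))
        n_selected.append(int(gbest.sum()))
        if cfg.target_error is not None and gbest_fitness <= cfg.target_error:
            break

    return SelectionRun(
        best_mask=gbest,
        best_fitness=gbest_fitness,
        history=history,
        mean_history=mean_history,
        n_selected_history=n_selected,
        config=cfg,
        selector="pso",
    )
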