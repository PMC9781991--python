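"""Binary genetic algorithm for wrapper feature selection.

A chromosome is a binary mask over feature-matrix columns (1 = column kept);
its fitness is the mean 10-fold cross-validated misclassification fraction
of the one-vs-all SVM trained on the masked matrix (lower is better).  The
simple GA uses roulette-wheel selection, two-point crossover and uniform
per-gene mutation, with elitism of one so the best-so-far error is
monotonically non-increasing.

Because roulette selection needs non-negative weights that favour *low*
error, fitnesses are transformed as ``weight_i = (max_error − error_i) + ε``
before sampling.  The all-zero chromosome (no features) is assigned the
worst possible fitness, 1.0, without touching the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import SvmSpec, cv_mean_error
from .errors import ParameterError, ShapeError
from .features import FeatureMatrix, select_columns


@dataclass(frozen=True)
class GaConfig:
    """Simple-GA settings (fixed operators: roulette / two-point / uniform)."""

    n_genes: int
    pop_size: int = 100
    mutation_rate: float = 0.02
    max_iterations: int = 100
    crossover_rate: float = 1.0
    elitism: int = 1
    target_error: float | None = None
    seed: int = 0
    cv_k: int = 10
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.pop_size < 2:
            raise ParameterError("pop_size must be >= 2")
        if not 0 <= self.mutation_rate <= 1:
            raise ParameterError("mutation_rate must be in [0, 1]")
        if not 0 <= self.crossover_rate <= 1:
            raise ParameterError("crossover_rate must be in [0, 1]")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")


@dataclass
class Chromosome:
    genes: np.ndarray
    fitness: float | None = None


@dataclass
class SelectionRun:
    """Outcome of a wrapper-selection search (GA or PSO)."""

    best_mask: np.ndarray
    best_fitness: float
    history: list[float]
    mean_history: list[float]
    n_selected_history: list[int]
    config: object
    selector: str

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.history)),
                "best_error": self.history,
                "mean_error": self.mean_history,
                "n_selected": self.n_selected_history,
            }
        )

    def write_log(self, path: str | Path) -> None:
        df = self.log_frame()
        df.insert(0, "selector", self.selector)
        df.to_csv(path, index=False)

    def write_mask(self, path: str | Path, columns=None) -> None:
        df = pd.DataFrame({"selected": self.best_mask.astype(int)})
        if columns is not None:
            df.insert(0, "channel", columns.get_level_values("channel"))
            df.insert(1, "predictor", columns.get_level_values("predictor"))
        df.to_csv(path, index=False)


class MaskFitness:
    """Cached fitness: mean CV error of the SVM on the masked matrix.

    The CV fold seed is fixed across evaluations so identical masks always
    receive identical fitness (required for caching and for comparing the
    search against an exhaustive oracle).
    """

    def __init__(self, m: FeatureMatrix, svm: SvmSpec, k: int = 10, seed: int = 0):
        self.m = m
        self.svm = svm
        self.k = k
        self.seed = seed
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=np.int8)
        key = mask.tobytes()
        if key not in self._cache:
            if not mask.any():
                self._cache[key] = 1.0  # empty feature set is unclassifiable
            else:
                sub = select_columns(self.m, mask)
                self._cache[key] = cv_mean_error(
                    sub, self.svm, k=self.k, seed=self.seed
                ).mean_error
                self.n_evaluations += 1
        return self._cache[key]


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def roulette_select(population: list[Chromosome], rng: np.random.Generator,
                    n: int = 2, eps: float = 1e-6) -> list[Chromosome]:
    """Sample ``n`` parents with probability proportional to
    (max_error − error) + ε."""
    fitnesses = np.array([c.fitness for c in population], dtype=float)
    if np.any(np.isnan(fitnesses)) or any(c.fitness is None for c in population):
        raise ParameterError("population must be fully evaluated before selection")
    weights = (fitnesses.max() - fitnesses) + eps
    probs = weights / weights.sum()
    idx = rng.choice(len(population), size=n, p=probs)
    return [population[i] for i in idx]


def two_point_crossover(
    p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap the gene segment [i, j) between two parents, i < j uniform."""
    if p1.shape != p2.shape:
        raise ShapeError("parents must have equal gene counts")
    n = p1.size
    if n < 2:
        raise ShapeError("crossover needs at least 2 genes")
    i, j = sorted(rng.choice(n + 1, size=2, replace=False))
    c1, c2 = p1.copy(), p2.copy()
    c1[i:j], c2[i:j] = p2[i:j], p1[i:j]
    return c1, c2


def uniform_mutation(genes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each gene independently with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise ParameterError("mutation rate must be in [0, 1]")
    flips = rng.random(genes.size) < rate
    out = genes.copy()
    out[flips] = 1 - out[flips]
    return out


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------


def run_ga(m: FeatureMatrix, svm: SvmSpec, cfg: GaConfig) -> SelectionRun:
    """Minimize the CV error over feature masks with the simple GA."""
    if cfg.n_genes != m.values.shape[1]:
        raise ShapeError(
            f"n_genes={cfg.n_genes} but the matrix has {m.values.shape[1]} columns"
        )
    fitness = MaskFitness(m, svm, k=cfg.cv_k, seed=cfg.cv_seed)
    rng = np.random.default_rng(cfg.seed)

    population = [
        Chromosome(genes=rng.integers(0, 2, size=cfg.n_genes, dtype=np.int8))
        for _ in range(cfg.pop_size)
    ]
    for c in population:
        c.fitness = fitness(c.genes)

    best = min(population, key=lambda c: c.fitness)
    best = Chromosome(best.genes.copy(), best.fitness)
    history: list[float] = []
    mean_history: list[float] = []
    n_selected: list[int] = []

    for _ in range(cfg.max_iterations):
        next_pop: list[Chromosome] = [Chromosome(best.genes.copy(), best.fitness)
                                      for _ in range(cfg.elitism)]
        while len(next_pop) < cfg.pop_size:
            pa, pb = roulette_select(population, rng)
            g1, g2 = pa.genes, pb.genes
            if rng.random() < cfg.crossover_rate:
                g1, g2 = two_point_crossover(g1, g2, rng)
            for g in (g1, g2):
                if len(next_pop) >= cfg.pop_size:
                    break
                child = Chromosome(genes=uniform_mutation(g, cfg.mutation_rate, rng))
                child.fitness = fitness(child.genes)
                next_pop.append(child)
        population = next_pop
        gen_best = min(population, key=lambda c: c.fitness)
        if gen_best.fitness < best.fitness:
            best = Chromosome(gen_best.genes.copy(), gen_best.fitness)
        history.append(best.fitness)
        mean_history.append(float(np.mean([c.fitness for c in population])))
        n_selected.append(int(best.genes.sum()))
        if cfg.target_error is not None and best.fitness <= cfg.target_error:
            break

    return SelectionRun(
        best_mask=best.genes.copy(),
        best_fitness=best.fitness,
        history=history,
        mean_history=mean_history,
        n_selected_history=n_selected,
        config=cfg,
        selector="ga",
    )
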