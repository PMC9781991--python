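"""Genetic-algorithm operators and the full wrapper-selection loop."""

import numpy as np
import pytest

from emgselect import GaConfig, SvmSpec, run_ga
from emgselect.errors import ParameterError, ShapeError
from emgselect.ga import (
    Chromosome,
    MaskFitness,
    roulette_select,
    two_point_crossover,
    uniform_mutation,
)
from tests.conftest import make_blob_matrix


def _pop(fitnesses):
    return [
        Chromosome(genes=np.zeros(4, dtype=np.int8), fitness=f) for f in fitnesses
    ]


def test_roulette_probabilities_proportional_to_weights():
    # weights (max - f) + eps = 0.3, 0.1, ~0 -> probabilities ~ 0.75, 0.25, 0
    pop = _pop([0.0, 0.2, 0.3])
    rng = np.random.default_rng(0)
    counts = np.zeros(3)
    for _ in range(5000):
        for parent in roulette_select(pop, rng):
            counts[[id(c) for c in pop].index(id(parent))] += 1
    freq = counts / counts.sum()
    assert freq[0] == pytest.approx(0.75, abs=0.02)
    assert freq[1] == pytest.approx(0.25, abs=0.02)
    assert freq[2] < 0.001


def test_roulette_uniform_when_fitnesses_equal():
    pop = _pop([0.4, 0.4, 0.4, 0.4])
    rng = np.random.default_rng(1)
    counts = np.zeros(4)
    n_draws = 10_000
    for _ in range(n_draws // 2):
        for parent in roulette_select(pop, rng):
            counts[[id(c) for c in pop].index(id(parent))] += 1
    p = 0.25
    sigma = np.sqrt(n_draws * p * (1 - p))
    assert np.all(np.abs(counts - n_draws * p) < 3 * sigma)


def test_roulette_requires_evaluated_population():
    pop = [Chromosome(genes=np.zeros(4, dtype=np.int8))]
    with pytest.raises(ParameterError):
        roulette_select(pop, np.random.default_rng(0))


def test_roulette_population_of_one():
    pop = _pop([0.3])
    a, b = roulette_select(pop, np.random.default_rng(0))
    assert a is pop[0] and b is pop[0]


class _FixedCuts:
    """Generator stub returning predetermined crossover cut points."""

    def __init__(self, i, j):
        self.cuts = np.array([i, j])

    def choice(self, n, size, replace):
        return self.cuts


def test_two_point_crossover_exact_cuts():
    p1 = np.zeros(6, dtype=np.int8)
    p2 = np.ones(6, dtype=np.int8)
    c1, c2 = two_point_crossover(p1, p2, _FixedCuts(2, 4))
    assert c1.tolist() == [0, 0, 1, 1, 0, 0]
    assert c2.tolist() == [1, 1, 0, 0, 1, 1]


def test_two_point_crossover_full_swap_boundary():
    p1 = np.zeros(6, dtype=np.int8)
    p2 = np.ones(6, dtype=np.int8)
    c1, c2 = two_point_crossover(p1, p2, _FixedCuts(0, 6))
    assert c1.tolist() == p2.tolist()
    assert c2.tolist() == p1.tolist()


def test_two_point_crossover_properties():
    rng = np.random.default_rng(2)
    p1 = rng.integers(0, 2, 30, dtype=np.int8)
    p2 = rng.integers(0, 2, 30, dtype=np.int8)
    c1, c2 = two_point_crossover(p1, p2, rng)
    # gene multiset preserved column-wise
    np.testing.assert_array_equal(c1 + c2, p1 + p2)
    # c1 differs from p1 only inside the swapped segment, where it equals p2
    diff = np.flatnonzero(c1 != p1)
    if diff.size:
        lo, hi = diff.min(), diff.max() + 1
        np.testing.assert_array_equal(c1[lo:hi], p2[lo:hi])
        np.testing.assert_array_equal(c2[lo:hi], p1[lo:hi])


def test_identical_parents_yield_identical_offspring():
    p = np.array([1, 0, 1, 1], dtype=np.int8)
    c1, c2 = two_point_crossover(p, p.copy(), np.random.default_rng(0))
    assert c1.tolist() == p.tolist() and c2.tolist() == p.tolist()


def test_crossover_length_mismatch_rejected():
    with pytest.raises(ShapeError):
        two_point_crossover(np.zeros(4, dtype=np.int8), np.zeros(5, dtype=np.int8),
                            np.random.default_rng(0))


def test_mutation_rate_extremes():
    genes = np.array([1, 0, 1, 0], dtype=np.int8)
    rng = np.random.default_rng(0)
    assert uniform_mutation(genes, 0.0, rng).tolist() == genes.tolist()
    assert uniform_mutation(genes, 1.0, rng).tolist() == [0, 1, 0, 1]


def test_mutation_flip_count_binomial():
    rng = np.random.default_rng(3)
    genes = np.zeros(104, dtype=np.int8)
    rate, n_trials = 0.02, 10_000
    flips = sum(int(uniform_mutation(genes, rate, rng).sum()) for _ in range(n_trials))
    expected = n_trials * 104 * rate
    sigma = np.sqrt(n_trials * 104 * rate * (1 - rate))
    assert abs(flips - expected) < 3 * sigma


def test_all_zero_mask_gets_worst_fitness_without_svm(blob6):
    m, _ = blob6
    fitness = MaskFitness(m, SvmSpec(), k=5, seed=0)
    assert fitness(np.zeros(6, dtype=np.int8)) == 1.0
    assert fitness.n_evaluations == 0


def test_fitness_cache_hits(blob6):
    m, _ = blob6
    fitness = MaskFitness(m, SvmSpec(), k=5, seed=0)
    mask = np.array([1, 0, 1, 0, 0, 0], dtype=np.int8)
    a, b = fitness(mask), fitness(mask)
    assert a == b and fitness.n_evaluations == 1


def test_run_ga_structure_and_reproducibility(blob6):
    m, _ = blob6
    cfg = GaConfig(n_genes=6, pop_size=8, mutation_rate=0.05, max_iterations=5,
                   seed=1, cv_k=5, cv_seed=0)
    run1 = run_ga(m, SvmSpec(), cfg)
    run2 = run_ga(m, SvmSpec(), cfg)
    assert len(run1.history) == 5
    np.testing.assert_array_equal(run1.best_mask, run2.best_mask)
    assert run1.history == run2.history
    # elitism: best-so-far never worsens
    assert all(a >= b for a, b in zip(run1.history, run1.history[1:]))


def test_run_ga_single_iteration_history(blob6):
    m, _ = blob6
    cfg = GaConfig(n_genes=6, pop_size=2, max_iterations=1, seed=0, cv_k=5)
    run = run_ga(m, SvmSpec(), cfg)
    assert len(run.history) == 1


def test_benchmark_ga_configuration_accepted():
    cfg = GaConfig(n_genes=104, pop_size=100, mutation_rate=0.02, max_iterations=100)
    assert cfg.pop_size == 100 and cfg.mutation_rate == 0.02


def test_gene_count_must_match_columns(blob6):
    m, _ = blob6
    with pytest.raises(ShapeError):
        run_ga(m, SvmSpec(), GaConfig(n_genes=7, pop_size=4, max_iterations=1))


def test_selection_log_round_trip(tmp_path, blob6):
    m, _ = blob6
    run = run_ga(m, SvmSpec(), GaConfig(n_genes=6, pop_size=4, max_iterations=2,
                                        seed=0, cv_k=5))
    run.write_log(tmp_path / "log.csv")
    run.write_mask(tmp_path / "mask.csv", m.columns)
    import pandas as pd

    log = pd.read_csv(tmp_path / "log.csv")
    assert list(log.columns) == ["selector", "generation", "best_error",
                                 "mean_error", "n_selected"]
    mask = pd.read_csv(tmp_path / "mask.csv")
    assert mask["selected"].tolist() == run.best_mask.astype(int).tolist()
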