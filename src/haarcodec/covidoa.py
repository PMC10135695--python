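"""COVIDOA: a coronavirus-replication-inspired continuous metaheuristic.

The optimizer minimizes a user-supplied objective over a box
``[lb, ub]^D``.  Each iteration, for every population slot, a parent is
chosen by binary tournament; ``num_proteins`` "viral proteins" are made
from it by +1 frameshifting (shift the genome forward, refill the freed
leading positions uniformly at random); the proteins are merged by
uniform crossover into a "virion", which then passes through per-gene
uniform-replacement mutation at rate ``MR``.  The virion replaces the
parent only if strictly fitter, so the best-so-far fitness never
increases.  A single seeded generator drives every operator, making runs
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

Objective = Callable[[np.ndarray], float]


class ObjectiveEvaluationError(RuntimeError):
    """The objective returned a non-finite value for some genome."""


@dataclass
class CovidoaConfig:
    """Parameters of the optimizer.

    Defaults follow the codec's standard settings: population 30,
    50 iterations, 2 proteins per parent, shift 1, mutation rate 0.5.
    """

    dimension: int
    lower_bound: float
    upper_bound: float
    population_size: int = 30
    max_iterations: int = 50
    num_proteins: int = 2
    shift_count: int = 1
    mutation_rate: float = 0.5
    tournament_size: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.population_size < 1 or self.max_iterations < 1:
            raise ValueError("population_size and max_iterations must be positive")
        if self.num_proteins < 2:
            raise ValueError("num_proteins must be >= 2")
        if self.shift_count < 1:
            raise ValueError("shift_count must be >= 1")
        if not 0.005 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation_rate must lie in [0.005, 0.5]")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")


@dataclass
class CandidateSolution:
    """A genome in ``[lb, ub]^D`` with its objective value (lower is better)."""

    genome: np.ndarray
    fitness: float


@dataclass
class OptimizationTrace:
    """Best-so-far fitness per iteration plus the final best solution."""

    best_fitness_per_iteration: np.ndarray
    best_solution: CandidateSolution
    evaluations: int

    def to_csv(self, path) -> None:
        rows = "\n".join(
            f"{i},{v!r}" for i, v in enumerate(self.best_fitness_per_iteration)
        )
        with open(path, "w") as fh:
            fh.write("iteration,best_fitness\n" + rows + "\n")


def _evaluate(objective: Objective, genome: np.ndarray) -> float:
    value = float(objective(genome))
    if not np.isfinite(value):
        raise ObjectiveEvaluationError(
            f"objective returned non-finite value {value!r} for genome {genome!r}"
        )
    return value


def initialize_population(
    config: CovidoaConfig,
    objective: Objective,
    rng: np.random.Generator | None = None,
) -> list[CandidateSolution]:
    """Draw ``population_size`` genomes i.i.d. uniform on the box, evaluate,
    and return them sorted ascending by fitness."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    genomes = rng.uniform(
        config.lower_bound,
        config.upper_bound,
        size=(config.population_size, config.dimension),
    )
    population = [CandidateSolution(g, _evaluate(objective, g)) for g in genomes]
    population.sort(key=lambda s: s.fitness)
    return population


def frameshift(
    parent: np.ndarray,
    config: CovidoaConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """+1 frameshifting: shift the parent genome forward by ``shift_count``
    positions and fill the freed leading positions uniformly at random."""
    p = np.asarray(parent, dtype=float)
    s = config.shift_count
    if s >= p.size:
        raise ValueError(
            f"shift_count {s} must be smaller than the genome length {p.size}"
        )
    child = np.empty_like(p)
    child[:s] = rng.uniform(config.lower_bound, config.upper_bound, size=s)
    child[s:] = p[: p.size - s]
    return child


def uniform_crossover(
    proteins: Sequence[np.ndarray],
    config: CovidoaConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Merge proteins gene-by-gene, each gene drawn from one protein
    uniformly at random."""
    mats = [np.asarray(p, dtype=float) for p in proteins]
    if len(mats) < 2:
        raise ValueError("uniform crossover needs at least two proteins")
    d = mats[0].size
    if any(m.size != d for m in mats):
        raise ValueError("all proteins must have equal genome length")
    choice = rng.integers(0, len(mats), size=d)
    stacked = np.stack(mats)
    return stacked[choice, np.arange(d)]


def mutate(
    solution: np.ndarray,
    config: CovidoaConfig,
    rng: np.random.Generator,
    mutation_rate: float | None = None,
) -> np.ndarray:
    """Per-gene mutation: with probability MR replace a gene with a fresh
    uniform draw from the box, otherwise keep it."""
    mr = config.mutation_rate if mutation_rate is None else mutation_rate
    z = np.asarray(solution, dtype=float).copy()
    mask = rng.random(z.size) < mr
    if mask.any():
        z[mask] = rng.uniform(config.lower_bound, config.upper_bound, size=mask.sum())
    return z


def optimize(objective: Objective, config: CovidoaConfig) -> OptimizationTrace:
    """Run the full optimizer loop and return its trace.

    The population update is synchronous within an iteration: parents are
    drawn from the population as it stood at the start of the iteration,
    and a virion replaces its parent slot only on strict improvement.
    """
    rng = np.random.default_rng(config.rng_seed)
    population = initialize_population(config, objective, rng)
    evaluations = config.population_size
    best = min(population, key=lambda s: s.fitness)
    best = CandidateSolution(best.genome.copy(), best.fitness)

    trace = np.empty(config.max_iterations)
    n = config.population_size
    for it in range(config.max_iterations):
        snapshot = list(population)
        for _ in range(n):
            idx = rng.integers(0, n, size=config.tournament_size)
            parent_idx = min(idx, key=lambda i: snapshot[i].fitness)
            parent = snapshot[parent_idx]
            if config.shift_count >= config.dimension:
                # degenerate frameshift: the shift would erase the whole
                # genome, so the protein is a fresh uniform draw
                proteins = [
                    rng.uniform(
                        config.lower_bound,
                        config.upper_bound,
                        size=config.dimension,
                    )
                    for _ in range(config.num_proteins)
                ]
            else:
                proteins = [
                    frameshift(parent.genome, config, rng)
                    for _ in range(config.num_proteins)
                ]
            virion = uniform_crossover(proteins, config, rng)
            virion = mutate(virion, config, rng)
            fitness = _evaluate(objective, virion)
            evaluations += 1
            if fitness < population[parent_idx].fitness:
                population[parent_idx] = CandidateSolution(virion, fitness)
                if fitness < best.fitness:
                    best = CandidateSolution(virion.copy(), fitness)
        trace[it] = best.fitness
    return OptimizationTrace(
        best_fitness_per_iteration=trace,
        best_solution=best,
        evaluations=evaluations,
    )
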