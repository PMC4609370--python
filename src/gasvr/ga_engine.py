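"""Real-coded genetic algorithm for simultaneous SVR tuning and feature selection.

Each individual carries a mixed chromosome: three bounded float genes —
the SVR hyperparameters C, gamma and epsilon — and a feature gene, an
array of k distinct column indices in [0, N). Fitness is the 10-fold
cross-validated MSE of the SVR trained on exactly those k features, so
hyperparameters and subset are optimized together rather than in separate
stages.

Operators follow common real-coded GA practice:

* tournament selection (best of 3 random candidates, drawn with replacement);
* blend crossover for float genes, child = beta*p1 + (1-beta)*p2 with beta
  uniform on [-0.25, 1.25], clamped to the gene bounds;
* uniform crossover for the feature gene with duplicate repair;
* float mutation moving a gene a random fraction of the way to its lower or
  upper bound; feature mutation replacing a slot with a uniform draw that
  avoids indices already present;
* elitism (best individuals copied unchanged) plus a fixed number of fresh
  random "immigrant" chromosomes per generation to maintain diversity.

Defaults mirror a typical configuration for this problem class:
population 100, 1000 generations, crossover rate 0.8, mutation rate 0.1,
2 elites and 8 immigrants per generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .datakit import FeatureTable, SplitResult, take_samples
from .errors import ConfigurationError, ValidationError
from .svr_fitness import SVMParams, cv_mse, cv_predict, make_folds, r_squared

__all__ = [
    "GeneBounds",
    "Chromosome",
    "Individual",
    "GAConfig",
    "GenerationRecord",
    "EvolutionHistory",
    "random_chromosome",
    "tournament_select",
    "blend_crossover_float",
    "uniform_crossover_features",
    "mutate_float",
    "mutate_features",
    "next_generation",
    "evolve",
    "run_replicates",
]

Bounds = tuple[float, float]


@dataclass(frozen=True)
class GeneBounds:
    """Allowed [min, max] range per float gene.

    Defaults bracket the hyperparameter ranges typically found useful for
    z-scored QSAR descriptors (C up to ~10^2, moderate RBF widths, a tube
    no wider than the target's spread).
    """

    C: Bounds = (0.01, 100.0)
    gamma: Bounds = (1e-4, 2.0)
    epsilon: Bounds = (0.001, 1.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("C", self.C), ("gamma", self.gamma), ("epsilon", self.epsilon)):
            if not lo < hi:
                raise ConfigurationError(f"{name} bounds must satisfy min < max")
        if self.C[0] <= 0 or self.gamma[0] <= 0:
            raise ConfigurationError("C and gamma bounds must be strictly positive")
        if self.epsilon[0] < 0:
            raise ConfigurationError("epsilon lower bound must be >= 0")


@dataclass(frozen=True)
class Chromosome:
    """Three float genes (as SVMParams) plus an ordered feature-index gene."""

    params: SVMParams
    features: tuple[int, ...]

    def __post_init__(self) -> None:
        feats = tuple(int(f) for f in self.features)
        object.__setattr__(self, "features", feats)
        if len(set(feats)) != len(feats):
            raise ValidationError("feature gene contains duplicate indices")
        if any(f < 0 for f in feats):
            raise ValidationError("feature indices must be non-negative")


@dataclass(frozen=True)
class Individual:
    chromosome: Chromosome
    fitness: float  # cv_mse; lower is better


@dataclass(frozen=True)
class GAConfig:
    """Every evolution parameter in one place; fully seeded."""

    k_features: int
    population_size: int = 100
    generations: int = 1000
    cross_rate: float = 0.8
    mutation_rate: float = 0.1
    elite_size: int = 2
    n_immigrants: int = 8
    tournament_size: int = 3
    bounds: GeneBounds = field(default_factory=GeneBounds)
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_features < 1:
            raise ConfigurationError("k_features must be >= 1")
        if self.population_size < 1 or self.generations < 0:
            raise ConfigurationError("population_size >= 1 and generations >= 0 required")
        if not (0.0 <= self.cross_rate <= 1.0 and 0.0 <= self.mutation_rate <= 1.0):
            raise ConfigurationError("rates must lie in [0, 1]")
        if self.elite_size < 0 or self.n_immigrants < 0:
            raise ConfigurationError("elite_size and n_immigrants must be >= 0")
        if self.elite_size + self.n_immigrants > self.population_size:
            raise ConfigurationError("elite_size + n_immigrants must not exceed population_size")
        if self.tournament_size < 1:
            raise ConfigurationError("tournament_size must be >= 1")


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    best_cv_mse: float
    mean_cv_mse: float


@dataclass(frozen=True)
class EvolutionHistory:
    """Per-generation fitness trace plus the all-time best individual."""

    records: tuple[GenerationRecord, ...]
    best_individual: Individual
    config: GAConfig

    def best_trace(self) -> np.ndarray:
        return np.array([r.best_cv_mse for r in self.records])

    def to_dict(self) -> dict:
        best = self.best_individual
        return {
            "config": asdict(self.config),
            "records": [asdict(r) for r in self.records],
            "best": {
                "C": best.chromosome.params.C,
                "gamma": best.chromosome.params.gamma,
                "epsilon": best.chromosome.params.epsilon,
                "features": list(best.chromosome.features),
                "cv_mse": best.fitness,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


# ---------------------------------------------------------------------------
# operators


def random_chromosome(
    config: GAConfig, n_total_features: int, rng: np.random.Generator
) -> Chromosome:
    """Uniform random chromosome: float genes within bounds, k distinct features."""
    if config.k_features > n_total_features:
        raise ConfigurationError("k_features exceeds the number of available features")
    b = config.bounds
    params = SVMParams(
        C=float(rng.uniform(*b.C)),
        gamma=float(rng.uniform(*b.gamma)),
        epsilon=float(rng.uniform(*b.epsilon)),
    )
    feats = tuple(int(i) for i in rng.choice(n_total_features, size=config.k_features, replace=False))
    return Chromosome(params=params, features=feats)


def tournament_select(
    population: Sequence[Individual], tournament_size: int, rng: np.random.Generator
) -> Individual:
    """Best-of-k tournament; candidates drawn with replacement, ties to the first drawn."""
    if not population:
        raise ValidationError("population is empty")
    best: Individual | None = None
    for _ in range(tournament_size):
        cand = population[int(rng.integers(len(population)))]
        if best is None or cand.fitness < best.fitness:
            best = cand
    assert best is not None
    return best


def blend_crossover_float(p1: float, p2: float, bounds: Bounds, beta: float) -> float:
    """Blend crossover: beta*p1 + (1-beta)*p2, clamped to the gene bounds.

    beta is drawn from uniform[-0.25, 1.25] by the caller, so the child can
    lie somewhat outside the parents' span before clamping.
    """
    lo, hi = bounds
    return float(min(max(beta * p1 + (1.0 - beta) * p2, lo), hi))


def uniform_crossover_features(
    f1: Sequence[int], f2: Sequence[int], n_total: int, rng: np.random.Generator
) -> tuple[int, ...]:
    """Position-wise coin flip between parents, with duplicate repair.

    Duplicated slots are refilled from the parents' unused indices when any
    remain (keeping offspring close to parental material), otherwise from a
    uniform draw over the rest of [0, N).
    """
    f1 = tuple(int(v) for v in f1)
    f2 = tuple(int(v) for v in f2)
    if len(f1) != len(f2):
        raise ValidationError("parent feature genes must have equal length")
    raw = [f1[i] if rng.random() < 0.5 else f2[i] for i in range(len(f1))]
    child: list[int | None] = []
    seen: set[int] = set()
    for v in raw:
        if v in seen:
            child.append(None)
        else:
            child.append(v)
            seen.add(v)
    parental_pool = sorted((set(f1) | set(f2)) - seen)
    for i, v in enumerate(child):
        if v is not None:
            continue
        if parental_pool:
            pick = parental_pool.pop(int(rng.integers(len(parental_pool))))
        else:
            rest = sorted(set(range(n_total)) - seen)
            pick = rest[int(rng.integers(len(rest)))]
        child[i] = pick
        seen.add(pick)
    return tuple(child)  # type: ignore[arg-type]


def mutate_float(v: float, bounds: Bounds, beta: float, direction_draw: float) -> float:
    """Move the gene a random fraction of the way to one of its bounds.

    Downward (direction_draw < 0.5): v - beta*(v - v_min); upward otherwise:
    v + beta*(v_max - v). With beta in [0, 1] the result stays in bounds.
    """
    lo, hi = bounds
    if direction_draw < 0.5:
        return float(v - beta * (v - lo))
    return float(v + beta * (hi - v))


def mutate_features(
    features: Sequence[int],
    n_total: int,
    mutation_rate: float,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    """Per-slot mutation replacing an index with a fresh one, avoiding duplicates.

    When k = N there is no legal replacement and the gene is returned
    unchanged.
    """
    feats = [int(v) for v in features]
    if len(feats) >= n_total:
        # draws still consumed per slot so operator sequencing stays seeded
        for _ in feats:
            rng.random()
        return tuple(feats)
    for i in range(len(feats)):
        if rng.random() < mutation_rate:
            present = set(feats)
            options = sorted(set(range(n_total)) - present)
            feats[i] = options[int(rng.integers(len(options)))]
    return tuple(feats)


# ---------------------------------------------------------------------------
# generation loop

FitnessFn = Callable[[Chromosome], float]


def _mate(
    c1: Chromosome, c2: Chromosome, config: GAConfig, n_total: int, rng: np.random.Generator
) -> Chromosome:
    b = config.bounds
    params = SVMParams(
        C=blend_crossover_float(c1.params.C, c2.params.C, b.C, float(rng.uniform(-0.25, 1.25))),
        gamma=blend_crossover_float(
            c1.params.gamma, c2.params.gamma, b.gamma, float(rng.uniform(-0.25, 1.25))
        ),
        epsilon=blend_crossover_float(
            c1.params.epsilon, c2.params.epsilon, b.epsilon, float(rng.uniform(-0.25, 1.25))
        ),
    )
    feats = uniform_crossover_features(c1.features, c2.features, n_total, rng)
    return Chromosome(params=params, features=feats)


def _mutate(
    c: Chromosome, config: GAConfig, n_total: int, rng: np.random.Generator
) -> Chromosome:
    b = config.bounds
    genes = {"C": (c.params.C, b.C), "gamma": (c.params.gamma, b.gamma), "epsilon": (c.params.epsilon, b.epsilon)}
    mutated = {}
    for name, (v, bounds) in genes.items():
        if rng.random() < config.mutation_rate:
            mutated[name] = mutate_float(v, bounds, float(rng.random()), float(rng.random()))
        else:
            mutated[name] = v
    feats = mutate_features(c.features, n_total, config.mutation_rate, rng)
    return Chromosome(params=SVMParams(**mutated), features=feats)


def next_generation(
    population: Sequence[Individual],
    config: GAConfig,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    n_total_features: int,
) -> list[Individual]:
    """Assemble the next population: elites + immigrants + bred offspring.

    Offspring come from two tournament-selected parents, mated with
    probability ``cross_rate`` (otherwise the fitter parent's chromosome is
    cloned), then mutated gene-wise at ``mutation_rate``.
    """
    if len(population) != config.population_size:
        raise ValidationError("population size does not match config")
    order = sorted(range(len(population)), key=lambda i: (population[i].fitness, i))
    new: list[Individual] = [population[i] for i in order[: config.elite_size]]
    for _ in range(config.n_immigrants):
        chrom = random_chromosome(config, n_total_features, rng)
        new.append(Individual(chrom, fitness_fn(chrom)))
    while len(new) < config.population_size:
        p1 = tournament_select(population, config.tournament_size, rng)
        p2 = tournament_select(population, config.tournament_size, rng)
        if rng.random() < config.cross_rate:
            child = _mate(p1.chromosome, p2.chromosome, config, n_total_features, rng)
        else:
            child = (p1 if p1.fitness <= p2.fitness else p2).chromosome
        child = _mutate(child, config, n_total_features, rng)
        new.append(Individual(child, fitness_fn(child)))
    return new


def fold_seed_for(seed: int) -> int:
    """The fold-assignment seed an evolve() run derives from its config seed."""
    return int(np.random.default_rng(seed).integers(2**31))


def evolve(
    table: FeatureTable,
    config: GAConfig,
    fitness_fn: FitnessFn | None = None,
) -> EvolutionHistory:
    """Run the genetic algorithm for ``config.generations`` generations.

    The CV fold assignment is fixed once per run (derived from the config
    seed), so fitness is a deterministic function of the chromosome within
    the run; repeated evaluations of an identical chromosome are served
    from a cache. The returned history records the population's best and
    mean cv_mse per generation (generation 0 is the random initial
    population) and the all-time best individual.
    """
    n_total = table.n_features
    if config.k_features > n_total:
        raise ConfigurationError("k_features exceeds the table's feature count")
    rng = np.random.default_rng(config.seed)
    folds = make_folds(table.sample_ids, config.n_folds, int(rng.integers(2**31)))

    if fitness_fn is None:
        cache: dict[tuple, float] = {}

        def fitness_fn(chrom: Chromosome) -> float:  # noqa: F811 - intentional default
            key = (chrom.params.C, chrom.params.gamma, chrom.params.epsilon, chrom.features)
            if key not in cache:
                cache[key] = cv_mse(table, chrom.features, chrom.params, folds=folds)
            return cache[key]

    population = []
    for _ in range(config.population_size):
        chrom = random_chromosome(config, n_total, rng)
        population.append(Individual(chrom, fitness_fn(chrom)))

    def _record(gen: int, pop: Sequence[Individual]) -> GenerationRecord:
        fits = np.array([ind.fitness for ind in pop])
        return GenerationRecord(gen, float(fits.min()), float(fits.mean()))

    best = min(population, key=lambda ind: ind.fitness)
    records = [_record(0, population)]
    for gen in range(1, config.generations + 1):
        population = next_generation(population, config, fitness_fn, rng, n_total)
        gen_best = min(population, key=lambda ind: ind.fitness)
        if gen_best.fitness < best.fitness:
            best = gen_best
        records.append(_record(gen, population))
    return EvolutionHistory(records=tuple(records), best_individual=best, config=config)


def _replicate_seed(base_seed: int, k: int, run: int) -> int:
    return int(np.random.SeedSequence([base_seed, k, run]).generate_state(1)[0] % 2**31)


def run_replicates(
    table: FeatureTable,
    config: GAConfig,
    n_runs: int,
    k_range: Iterable[int],
    split: SplitResult | None = None,
):
    """Replicate GA runs over a sweep of subset sizes k.

    For each k, runs ``n_runs`` independently seeded evolutions (seeds
    derived deterministically from ``config.seed``, k and the run index)
    and keeps the replicate with the lowest cv_mse. When a train/test
    ``split`` is supplied, evolution happens on the training partition and
    the summary additionally reports train/test r^2 for each per-k winner.

    Returns ``(histories, summary)`` where ``histories`` maps k to the list
    of EvolutionHistory objects and ``summary`` is a pandas DataFrame with
    one row per k (k, cv_mse, cv_r2, train_r2, test_r2, C, gamma, epsilon).
    """
    import pandas as pd

    from .model_analysis import evaluate_final_model

    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    work_table = table if split is None else take_samples(table, split.train_indices)

    histories: dict[int, list[EvolutionHistory]] = {}
    rows = []
    for k in k_range:
        runs = []
        for r in range(n_runs):
            cfg = replace(config, k_features=int(k), seed=_replicate_seed(config.seed, int(k), r))
            runs.append(evolve(work_table, cfg))
        histories[int(k)] = runs
        winner = min(runs, key=lambda h: h.best_individual.fitness)
        chrom = winner.best_individual.chromosome
        folds = make_folds(work_table.sample_ids, config.n_folds, fold_seed_for(winner.config.seed))
        cv_pred = cv_predict(work_table, chrom.features, chrom.params, folds=folds)
        row = {
            "k": int(k),
            "cv_mse": winner.best_individual.fitness,
            "cv_r2": r_squared(cv_pred, work_table.y),
            "train_r2": np.nan,
            "test_r2": np.nan,
            "C": chrom.params.C,
            "gamma": chrom.params.gamma,
            "epsilon": chrom.params.epsilon,
        }
        if split is not None:
            report = evaluate_final_model(table, split, chrom, n_folds=config.n_folds, seed=config.seed)
            row["train_r2"] = report["train_r2"]
            row["test_r2"] = report.get("test_r2", np.nan)
        rows.append(row)
    summary = pd.DataFrame(rows)
    return histories, summary
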