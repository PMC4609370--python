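"""GA operators, generation assembly and end-to-end evolution behaviour."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gasvr import (
    Chromosome,
    GAConfig,
    GeneBounds,
    Individual,
    SVMParams,
    cv_mse,
    evolve,
    make_folds,
    run_replicates,
)
from gasvr.errors import ConfigurationError, ValidationError
from gasvr.ga_engine import (
    blend_crossover_float,
    fold_seed_for,
    mutate_features,
    mutate_float,
    next_generation,
    random_chromosome,
    tournament_select,
    uniform_crossover_features,
)
from gasvr.synthetic import SyntheticSpec, generate, with_relative_noise

from conftest import make_table


def mock_fitness(chrom: Chromosome) -> float:
    """Cheap deterministic stand-in fitness for mechanics tests."""
    return float(sum(chrom.features)) + chrom.params.C * 1e-6


def mock_population(config, n_total, seed=0):
    rng = np.random.default_rng(seed)
    pop = []
    for _ in range(config.population_size):
        c = random_chromosome(config, n_total, rng)
        pop.append(Individual(c, mock_fitness(c)))
    return pop


class TestBlendCrossover:
    def test_endpoints_and_midpoint(self):
        b = (0.0, 100.0)
        assert blend_crossover_float(10.0, 20.0, b, beta=1.0) == 10.0
        assert blend_crossover_float(10.0, 20.0, b, beta=0.0) == 20.0
        assert blend_crossover_float(10.0, 20.0, b, beta=0.5) == 15.0

    def test_clamped_to_bounds(self):
        b = (0.0, 100.0)
        assert blend_crossover_float(100.0, 50.0, b, beta=1.25) == 100.0
        assert blend_crossover_float(0.0, 50.0, b, beta=1.25) == 0.0

    @given(
        p=st.floats(0.0, 1.0),
        q=st.floats(0.0, 1.0),
        beta=st.floats(-0.25, 1.25),
    )
    def test_always_within_bounds(self, p, q, beta):
        lo, hi = 0.01, 2.0
        p1 = lo + p * (hi - lo)
        p2 = lo + q * (hi - lo)
        assert lo <= blend_crossover_float(p1, p2, (lo, hi), beta) <= hi


class TestFloatMutation:
    def test_beta_zero_is_identity(self):
        assert mutate_float(5.0, (0.0, 10.0), beta=0.0, direction_draw=0.2) == 5.0
        assert mutate_float(5.0, (0.0, 10.0), beta=0.0, direction_draw=0.9) == 5.0

    def test_beta_one_hits_bounds(self):
        assert mutate_float(5.0, (1.0, 10.0), beta=1.0, direction_draw=0.0) == 1.0
        assert mutate_float(5.0, (1.0, 10.0), beta=1.0, direction_draw=0.9) == 10.0

    @given(
        v=st.floats(0.0, 1.0),
        beta=st.floats(0.0, 1.0),
        direction=st.floats(0.0, 1.0),
    )
    def test_always_within_bounds(self, v, beta, direction):
        lo, hi = 0.5, 3.5
        out = mutate_float(lo + v * (hi - lo), (lo, hi), beta, direction)
        assert lo <= out <= hi


class TestFeatureMutation:
    def test_zero_rate_identity(self, rng):
        assert mutate_features((3, 1, 4), 10, 0.0, rng) == (3, 1, 4)

    def test_only_legal_replacement(self, rng):
        # k=1, N=2: a forced mutation of (0,) must give (1,)
        assert mutate_features((0,), 2, 1.0, rng) == (1,)

    def test_full_gene_unchanged_when_k_equals_n(self, rng):
        assert mutate_features((0, 1, 2), 3, 1.0, rng) == (0, 1, 2)

    def test_replacement_avoids_present_indices(self, rng):
        """Exhaustive legality check of forced single-position mutations."""
        for _ in range(300):
            out = mutate_features((0, 1), 5, 1.0, rng)
            assert len(set(out)) == 2
            assert all(0 <= v < 5 for v in out)
            # a mutated slot never receives an index that was already present
            if out[0] != 0:
                assert out[0] in {2, 3, 4}


class TestUniformCrossover:
    def test_identical_parents(self, rng):
        assert uniform_crossover_features((1, 2, 3), (1, 2, 3), 10, rng) == (1, 2, 3)

    def test_child_always_valid(self, rng):
        """Repair enumeration: every outcome is k distinct in-range indices."""
        f1, f2 = (0, 1), (1, 2)
        seen = set()
        for _ in range(500):
            child = uniform_crossover_features(f1, f2, 4, rng)
            assert len(child) == 2 and len(set(child)) == 2
            assert all(0 <= v < 4 for v in child)
            seen.add(tuple(sorted(child)))
        # the overlap element 1 plus one distinct partner must be reachable
        assert any(1 in c for c in seen)

    def test_disjoint_parents_draw_from_both(self, rng):
        f1, f2 = (0, 1, 2), (5, 6, 7)
        child = uniform_crossover_features(f1, f2, 10, rng)
        assert set(child) <= set(f1) | set(f2)

    def test_unequal_length_rejected(self, rng):
        with pytest.raises(ValidationError):
            uniform_crossover_features((1,), (1, 2), 5, rng)


class TestRandomChromosome:
    def test_deterministic_given_seed(self):
        cfg = GAConfig(k_features=3)
        a = random_chromosome(cfg, 20, np.random.default_rng(9))
        b = random_chromosome(cfg, 20, np.random.default_rng(9))
        assert a == b

    def test_k_equals_n_gives_full_set(self, rng):
        cfg = GAConfig(k_features=5)
        c = random_chromosome(cfg, 5, rng)
        assert sorted(c.features) == [0, 1, 2, 3, 4]

    def test_feature_draws_uniform(self, rng):
        cfg = GAConfig(k_features=1)
        counts = np.zeros(4)
        n = 10_000
        for _ in range(n):
            counts[random_chromosome(cfg, 4, rng).features[0]] += 1
        sigma = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - n / 4) < 3 * sigma)

    def test_genes_within_bounds(self, rng):
        cfg = GAConfig(k_features=2)
        for _ in range(200):
            c = random_chromosome(cfg, 10, rng)
            assert cfg.bounds.C[0] <= c.params.C <= cfg.bounds.C[1]
            assert cfg.bounds.gamma[0] <= c.params.gamma <= cfg.bounds.gamma[1]
            assert cfg.bounds.epsilon[0] <= c.params.epsilon <= cfg.bounds.epsilon[1]

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            random_chromosome(GAConfig(k_features=6), 5, rng)


class TestTournament:
    def _ind(self, fit):
        return Individual(Chromosome(SVMParams(1, 1, 0.1), (0,)), fit)

    def test_population_of_one(self, rng):
        pop = [self._ind(0.5)]
        assert tournament_select(pop, 3, rng) is pop[0]

    def test_best_of_three_wins(self):
        pop = [self._ind(0.9), self._ind(0.1), self._ind(0.5)]

        class FakeRng:
            draws = iter([0, 1, 2])

            def integers(self, n):
                return next(self.draws)

        assert tournament_select(pop, 3, FakeRng()).fitness == 0.1

    def test_tie_goes_to_first_drawn(self):
        pop = [self._ind(0.5), self._ind(0.5), self._ind(0.5)]

        class FakeRng:
            draws = iter([2, 0, 1])

            def integers(self, n):
                return next(self.draws)

        assert tournament_select(pop, 3, FakeRng()) is pop[2]


class TestNextGeneration:
    def test_identity_evolution(self, rng):
        cfg = GAConfig(
            k_features=2, population_size=6, cross_rate=0.0, mutation_rate=0.0,
            elite_size=6, n_immigrants=0,
        )
        pop = mock_population(cfg, 10)
        new = next_generation(pop, cfg, mock_fitness, rng, 10)
        assert sorted(i.fitness for i in new) == sorted(i.fitness for i in pop)

    def test_elites_survive(self, rng):
        cfg = GAConfig(k_features=2, population_size=12, elite_size=2, n_immigrants=2)
        pop = mock_population(cfg, 30)
        best_two = sorted(i.fitness for i in pop)[:2]
        new = next_generation(pop, cfg, mock_fitness, rng, 30)
        new_fits = [i.fitness for i in new]
        assert all(f in new_fits for f in best_two)

    def test_offspring_count(self, rng):
        cfg = GAConfig(k_features=2, population_size=12, elite_size=2, n_immigrants=2)
        pop = mock_population(cfg, 30)
        calls = []

        def counting_fitness(c):
            calls.append(c)
            return mock_fitness(c)

        new = next_generation(pop, cfg, counting_fitness, rng, 30)
        assert len(new) == 12
        # 2 immigrants + 8 offspring evaluated; elites reused
        assert len(calls) == 10

    def test_immigrants_make_independent_generations(self):
        """With elite 0 and all-immigrant generations, selection pressure vanishes."""
        cfg = GAConfig(
            k_features=1, population_size=40, elite_size=0, n_immigrants=40,
            tournament_size=3,
        )
        rng = np.random.default_rng(0)
        # fitness strongly prefers feature 0; immigrants must ignore it
        pref = lambda c: 0.0 if c.features[0] == 0 else 1.0
        pop = mock_population(cfg, 4)
        hits = 0
        gens = 50
        for _ in range(gens):
            pop = next_generation(pop, cfg, pref, rng, 4)
            hits += sum(1 for i in pop if i.chromosome.features[0] == 0)
        n = gens * cfg.population_size
        sigma = np.sqrt(n * 0.25 * 0.75)
        assert abs(hits - 0.25 * n) < 4 * sigma


class TestChromosomeClosure:
    @given(seed=st.integers(0, 200))
    def test_operator_sequences_preserve_validity(self, seed):
        """Random chains of crossover/mutation always yield valid chromosomes."""
        rng = np.random.default_rng(seed)
        cfg = GAConfig(k_features=4, population_size=4, elite_size=0, n_immigrants=0)
        n_total = 12
        a = random_chromosome(cfg, n_total, rng)
        b = random_chromosome(cfg, n_total, rng)
        for _ in range(10):
            feats = uniform_crossover_features(a.features, b.features, n_total, rng)
            feats = mutate_features(feats, n_total, 0.5, rng)
            params = SVMParams(
                C=mutate_float(
                    blend_crossover_float(a.params.C, b.params.C, cfg.bounds.C,
                                          float(rng.uniform(-0.25, 1.25))),
                    cfg.bounds.C, float(rng.random()), float(rng.random()),
                ),
                gamma=a.params.gamma,
                epsilon=b.params.epsilon,
            )
            child = Chromosome(params, feats)  # constructor revalidates
            assert len(set(child.features)) == cfg.k_features
            assert all(0 <= f < n_total for f in child.features)
            assert cfg.bounds.C[0] <= child.params.C <= cfg.bounds.C[1]
            a, b = b, child


@pytest.fixture(scope="module")
def small_recovery_table():
    spec = SyntheticSpec(
        n_samples=120,
        n_features=15,
        informative_indices=(0, 4),
        effect_sizes=(-1.0, 1.0),
        n_binary_indicators=1,
        seed=11,
    )
    table, truth = generate(with_relative_noise(spec, 0.1))
    return table, truth


class TestEvolve:
    def test_zero_generations_returns_initial_best(self, small_recovery_table):
        table, _ = small_recovery_table
        cfg = GAConfig(k_features=2, population_size=8, generations=0, n_folds=5, seed=5,
                       elite_size=2, n_immigrants=2)
        h = evolve(table, cfg)
        assert len(h.records) == 1
        assert h.best_individual.fitness == h.records[0].best_cv_mse

    def test_same_seed_identical_history(self, small_recovery_table):
        table, _ = small_recovery_table
        cfg = GAConfig(k_features=2, population_size=10, generations=3, n_folds=5, seed=7)
        assert evolve(table, cfg).to_json() == evolve(table, cfg).to_json()

    def test_best_trace_non_increasing(self, small_recovery_table):
        table, _ = small_recovery_table
        cfg = GAConfig(k_features=2, population_size=12, generations=8, n_folds=5, seed=2)
        trace = evolve(table, cfg).best_trace()
        assert np.all(np.diff(trace) <= 0.0)

    def test_recovers_planted_pair_in_majority_of_runs(self, small_recovery_table):
        """Wrapper selection finds the informative pair from 15 candidates."""
        table, truth = small_recovery_table
        hits = 0
        for i in range(5):
            cfg = GAConfig(
                k_features=2, population_size=20, generations=40, n_folds=5,
                seed=100 + i,
            )
            h = evolve(table, cfg)
            if sorted(h.best_individual.chromosome.features) == sorted(
                truth.informative_indices
            ):
                hits += 1
        assert hits >= 3

    def test_small_instance_matches_exhaustive_oracle(self, rng):
        """GA cv_mse within 5% of the pairs x coarse-grid global optimum (N=8)."""
        X = rng.normal(size=(60, 8))
        y = 1.5 * X[:, 2] - X[:, 6] + rng.normal(0, 0.1, 60)
        table = make_table(X, y)
        cfg = GAConfig(k_features=2, population_size=20, generations=50, n_folds=5, seed=4)
        h = evolve(table, cfg)
        folds = make_folds(table.sample_ids, 5, fold_seed_for(cfg.seed))
        coarse = [
            SVMParams(C, g, e)
            for C in (1.0, 10.0, 100.0)
            for g in (0.1, 0.5)
            for e in (0.05, 0.2)
        ]
        oracle = min(
            cv_mse(table, pair, p, folds=folds)
            for pair in itertools.combinations(range(8), 2)
            for p in coarse
        )
        assert h.best_individual.fitness <= 1.05 * oracle


class TestRunReplicates:
    def test_single_run_summary(self, small_recovery_table):
        table, _ = small_recovery_table
        cfg = GAConfig(k_features=2, population_size=8, generations=2, n_folds=5, seed=3,
                       elite_size=2, n_immigrants=2)
        histories, summary = run_replicates(table, cfg, 1, [2])
        assert len(summary) == 1
        assert summary.loc[0, "k"] == 2
        assert summary.loc[0, "cv_mse"] == histories[2][0].best_individual.fitness

    def test_per_k_best_is_minimum(self, small_recovery_table):
        table, _ = small_recovery_table
        cfg = GAConfig(k_features=2, population_size=8, generations=2, n_folds=5, seed=3,
                       elite_size=2, n_immigrants=2)
        histories, summary = run_replicates(table, cfg, 3, [2])
        fits = [h.best_individual.fitness for h in histories[2]]
        assert summary.loc[0, "cv_mse"] == min(fits)

    def test_identical_base_seed_identical_summary(self, small_recovery_table):
        table, _ = small_recovery_table
        cfg = GAConfig(k_features=2, population_size=8, generations=2, n_folds=5, seed=3,
                       elite_size=2, n_immigrants=2)
        _, s1 = run_replicates(table, cfg, 2, [2, 3])
        _, s2 = run_replicates(table, cfg, 2, [2, 3])
        assert s1.equals(s2)


class TestGAConfigValidation:
    def test_elites_plus_immigrants_bounded(self):
        with pytest.raises(ConfigurationError):
            GAConfig(k_features=2, population_size=5, elite_size=3, n_immigrants=3)

    def test_rates_in_unit_interval(self):
        with pytest.raises(ConfigurationError):
            GAConfig(k_features=2, cross_rate=1.2)

    def test_bounds_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            GeneBounds(C=(5.0, 1.0))
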