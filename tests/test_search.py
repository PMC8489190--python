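import numpy as np
import pytest

from anonlattice import (AnonymizationContext, GAConfig, KAnonymity,
                         SearchBudget, evaluate_scheme, search_exhaustive,
                         search_genetic, search_greedy, triangle_init)
from anonlattice.search import Individual, next_generation

from conftest import random_instance


def ctx_for(ds, k=3):
    return AnonymizationContext(ds, KAnonymity(k))


class TestEvaluateScheme:
    @pytest.mark.parametrize("k,scheme,quality,suppressed", [
        (3, (2, 0), 50.0, 0),
        (3, (0, 0), 0.0, 8),
        (2, (0, 0), 100.0, 0),
    ])
    def test_toy_examples(self, toy, k, scheme, quality, suppressed):
        q, t = evaluate_scheme(ctx_for(toy, k), scheme)
        assert q == pytest.approx(quality)
        assert t.n_suppressed == suppressed

    def test_memoization_consistency(self, toy):
        ctx = ctx_for(toy)
        q1 = ctx.evaluate((1, 0))
        q2 = ctx.evaluate((1, 0))
        assert q1 == q2
        assert ctx.evaluations == 1

    def test_fast_path_matches_transform_layer(self):
        # the integer-coded evaluation must agree with the string pipeline
        from anonlattice import (PopulationUniqueness, apply_scheme,
                                 quality_granularity, suppress_to_satisfy)
        rng = np.random.default_rng(55)
        models = [KAnonymity(3), KAnonymity(5),
                  PopulationUniqueness(0.1, 0.5)]
        for trial in range(12):
            ds = random_instance(rng, max_attrs=3, max_records=60)
            model = models[trial % len(models)]
            ctx = AnonymizationContext(ds, model)
            g = tuple(int(rng.integers(0, h + 1)) for h in ds.heights)
            fast = ctx.evaluate(g)
            t = suppress_to_satisfy(apply_scheme(ds, g), model)
            slow = quality_granularity(ds, t)
            assert fast == pytest.approx(slow, abs=1e-9)
            assert ctx.materialize(g).suppressed == t.suppressed


class TestExhaustive:
    def test_toy_k3_optimum(self, toy):
        res = search_exhaustive(ctx_for(toy, 3))
        assert (res.scheme, res.quality) == ((2, 0), pytest.approx(50.0))

    def test_toy_k2_optimum(self, toy):
        res = search_exhaustive(ctx_for(toy, 2))
        assert (res.scheme, res.quality) == ((0, 0), pytest.approx(100.0))

    def test_single_attribute_k1(self):
        import pandas as pd
        from anonlattice import AttributeDefinition, Dataset, Role
        from anonlattice import GeneralizationHierarchy
        h = GeneralizationHierarchy("v", (("a", "x", "*"), ("b", "x", "*"),
                                          ("c", "y", "*")))
        ds = Dataset((AttributeDefinition("v", Role.QUASI_IDENTIFYING, h),),
                     pd.DataFrame({"v": ["a", "b", "c"]}, dtype=object))
        res = search_exhaustive(AnonymizationContext(ds, KAnonymity(1)))
        assert (res.scheme, res.quality) == ((0,), 100.0)

    def test_cap_exceeded_advises_heuristic(self):
        rng = np.random.default_rng(0)
        ds = random_instance(rng, max_attrs=4, max_records=20)
        with pytest.raises(ValueError, match="heuristic"):
            search_exhaustive(ctx_for(ds), cap=1)


class TestGreedy:
    @pytest.mark.parametrize("direction", ["bottom_up", "top_down"])
    def test_toy_exhaustion_equals_oracle(self, toy, direction):
        res = search_greedy(ctx_for(toy, 3), direction)
        assert (res.scheme, res.quality) == ((2, 0), pytest.approx(50.0))

    def test_evaluation_budget_contract(self, toy):
        ctx = ctx_for(toy, 3)
        res = search_greedy(ctx, "bottom_up",
                            SearchBudget(max_evaluations=1))
        assert res.evaluations == 1
        assert res.scheme == (0, 0)

    def test_oracle_equivalence_random_instances(self):
        # both directions run to exhaustion return the exhaustive optimum
        rng = np.random.default_rng(77)
        for _ in range(20):
            ds = random_instance(rng, max_records=100)
            opt = search_exhaustive(ctx_for(ds, 3))
            for direction in ("bottom_up", "top_down"):
                res = search_greedy(ctx_for(ds, 3), direction)
                assert res.quality == pytest.approx(opt.quality, abs=1e-9)
                assert res.scheme == opt.scheme

    def test_budgeted_quality_never_exceeds_oracle(self):
        rng = np.random.default_rng(78)
        for _ in range(8):
            ds = random_instance(rng, max_records=60)
            opt = search_exhaustive(ctx_for(ds, 3))
            for direction in ("bottom_up", "top_down"):
                res = search_greedy(ctx_for(ds, 3), direction,
                                    SearchBudget(max_evaluations=5))
                assert res.quality <= opt.quality + 1e-9

    def test_trace_monotone(self, toy):
        res = search_greedy(ctx_for(toy, 3), "bottom_up")
        best = [p.best_quality for p in res.trace]
        assert best == sorted(best)


class TestTriangleInit:
    def test_staircase_pattern(self):
        assert triangle_init([3, 1, 5, 3, 1], 10) == [
            (0, 0, 0, 0, 0), (3, 0, 0, 0, 0), (3, 1, 0, 0, 0),
            (3, 1, 5, 0, 0), (3, 1, 5, 3, 0), (3, 1, 5, 3, 1)]

    def test_truncated_by_count(self):
        assert triangle_init([2], 5) == [(0,), (2,)]
        assert triangle_init([3, 1, 5], 1) == [(0, 0, 0)]


class TestNextGeneration:
    def heights(self):
        return (3,) * 16

    def make_pop(self, rng, s=50):
        heights = self.heights()
        pop = [Individual(tuple(int(rng.integers(0, h + 1)) for h in heights))
               for _ in range(s)]
        return pop

    @staticmethod
    def fitness(genes):
        return -float(sum(genes))  # prefer low generalization, deterministic

    def test_default_fraction_counts(self):
        cfg = GAConfig()
        assert (cfg.n_elite, cfg.n_crossover, cfg.n_producers) == (10, 20, 10)
        assert cfg.mutation_bound(16) == 1

    def test_elite_preserved_and_size_kept(self):
        rng = np.random.default_rng(2)
        pop = self.make_pop(rng)
        nxt = next_generation(pop, GAConfig(), np.random.default_rng(0),
                              self.heights(), self.fitness)
        assert len(nxt) == 50
        best_in = sorted(pop, key=lambda i: (-self.fitness(i.genes), i.genes))
        assert [i.genes for i in nxt[:10]] == \
            [i.genes for i in best_in[:10]]

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(2)
        pop = self.make_pop(rng)
        a = next_generation([Individual(i.genes) for i in pop], GAConfig(),
                            np.random.default_rng(9), self.heights(),
                            self.fitness)
        b = next_generation([Individual(i.genes) for i in pop], GAConfig(),
                            np.random.default_rng(9), self.heights(),
                            self.fitness)
        assert [i.genes for i in a] == [i.genes for i in b]


class TestGenetic:
    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_finds_optimum_on_tiny_lattice(self, toy, seed):
        res = search_genetic(ctx_for(toy, 3), seed=seed)
        assert (res.scheme, res.quality) == ((2, 0), pytest.approx(50.0))
        res = search_genetic(ctx_for(toy, 2), seed=seed)
        assert (res.scheme, res.quality) == ((0, 0), pytest.approx(100.0))

    def test_full_elite_keeps_population_constant(self, toy):
        cfg = GAConfig(elite_fraction=1.0, crossover_fraction=0.0,
                       iterations=5)
        res = search_genetic(ctx_for(toy, 3), cfg, seed=3)
        # only initialization evaluates anything new
        assert res.evaluations <= 6  # toy lattice has 6 schemes

    def test_same_seed_identical_trace(self):
        rng = np.random.default_rng(9)
        ds = random_instance(rng, max_attrs=4, max_records=80)
        cfg = GAConfig(iterations=5, subpopulation_size=10)
        runs = []
        for _ in range(2):
            res = search_genetic(AnonymizationContext(ds, KAnonymity(3)),
                                 cfg, seed=7)
            runs.append([(p.evaluations, p.best_quality, p.best_scheme)
                         for p in res.trace])
        assert runs[0] == runs[1]

    def test_elitism_best_fitness_nondecreasing(self):
        # the per-subpopulation best never regresses across generations
        rng = np.random.default_rng(10)
        heights = (3, 3, 2, 2)
        pop = [Individual(tuple(int(rng.integers(0, h + 1)) for h in heights))
               for _ in range(12)]
        cfg = GAConfig(subpopulation_size=12, iterations=1)
        fit = lambda g: -float(sum((x - 2) ** 2 for x in g))
        g_rng = np.random.default_rng(4)
        bests = []
        for _ in range(10):
            for ind in pop:
                ind.fitness = ind.fitness or fit(ind.genes)
            bests.append(max(fit(i.genes) for i in pop))
            pop = next_generation(pop, cfg, g_rng, heights, fit)
        assert bests == sorted(bests)

    def test_quality_never_exceeds_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            ds = random_instance(rng, max_attrs=3, max_records=60)
            opt = search_exhaustive(ctx_for(ds, 3))
            cfg = GAConfig(iterations=3, subpopulation_size=8)
            res = search_genetic(ctx_for(ds, 3), cfg, seed=1)
            assert res.quality <= opt.quality + 1e-9
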