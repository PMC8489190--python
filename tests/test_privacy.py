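import numpy as np
import pytest

from anonlattice import (EquivalenceClassHistogram, KAnonymity,
                         PopulationUniqueness, apply_scheme, check_k_anonymity,
                         estimate_population_uniqueness, fit_pitman,
                         is_satisfied, suppress_to_satisfy, toy8)
from anonlattice.privacy import (expected_classes, expected_singletons,
                                 sample_pitman_partition)


def hist(*sizes):
    return EquivalenceClassHistogram(tuple(sizes))


class TestKAnonymity:
    def test_satisfied(self):
        assert check_k_anonymity(hist(3, 3, 4), 3)

    def test_violated(self):
        assert not check_k_anonymity(hist(3, 3, 4), 5)

    def test_empty_histogram_vacuously_true(self):
        assert check_k_anonymity(hist(), 10)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            check_k_anonymity(hist(1), 0)

    def test_lattice_monotone_without_suppression(self):
        # satisfied at g implies satisfied at every comparable g' >= g
        from conftest import random_instance
        rng = np.random.default_rng(21)
        for _ in range(15):
            ds = random_instance(rng, max_records=60)
            heights = ds.heights
            g = tuple(int(rng.integers(0, h + 1)) for h in heights)
            gp = tuple(int(rng.integers(gi, h + 1))
                       for gi, h in zip(g, heights))
            from anonlattice import equivalence_classes
            hg, _ = equivalence_classes(apply_scheme(ds, g))
            hgp, _ = equivalence_classes(apply_scheme(ds, gp))
            if check_k_anonymity(hg, 3):
                assert check_k_anonymity(hgp, 3)


class TestPitmanMoments:
    def test_single_draw_has_one_class(self):
        assert expected_classes(1, 50.0, 0.3) == pytest.approx(1.0)
        assert expected_singletons(1, 50.0, 0.3) == pytest.approx(1.0)

    def test_formulas_match_simulation(self):
        # the moment formulas against the sequential-construction oracle
        rng = np.random.default_rng(5)
        for theta, alpha in [(20.0, 0.0), (20.0, 0.4)]:
            n = 500
            sims = [sample_pitman_partition(n, theta, alpha, rng)
                    for _ in range(200)]
            mean_k = np.mean([h.n_classes for h in sims])
            mean_k1 = np.mean([h.n_singletons for h in sims])
            assert mean_k == pytest.approx(
                expected_classes(n, theta, alpha), rel=0.05)
            assert mean_k1 == pytest.approx(
                expected_singletons(n, theta, alpha), rel=0.10)


class TestPitmanFit:
    def test_all_singletons_hits_boundary_without_crash(self):
        fit = fit_pitman(hist(*([1] * 50)))
        assert not fit.converged
        assert 0.0 <= fit.alpha < 1.0

    def test_no_singletons_degenerate(self):
        fit = fit_pitman(hist(5, 5, 5))
        assert not fit.converged

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            fit_pitman(hist())

    @pytest.mark.parametrize("theta,alpha", [(100.0, 0.3), (50.0, 0.0)])
    def test_parameter_recovery_from_simulation(self, theta, alpha):
        # median over 25 replicates within 20% relative error of truth
        rng = np.random.default_rng(17)
        thetas, alphas = [], []
        for _ in range(25):
            h = sample_pitman_partition(5000, theta, alpha, rng)
            fit = fit_pitman(h)
            thetas.append(fit.theta)
            alphas.append(fit.alpha)
        assert abs(np.median(thetas) - theta) <= 0.2 * theta
        if alpha > 0:
            assert abs(np.median(alphas) - alpha) <= 0.2 * alpha
        else:
            assert np.median(alphas) <= 0.05


class TestUniquenessEstimate:
    def test_full_population_short_circuit_exact(self):
        assert estimate_population_uniqueness(hist(1, 1, 2), 1.0) == 0.5

    def test_no_singletons_estimate_zero(self):
        assert estimate_population_uniqueness(hist(2, 3, 4), 0.1) == 0.0

    def test_invalid_sampling_fraction(self):
        with pytest.raises(ValueError):
            estimate_population_uniqueness(hist(1, 2), 0.0)
        with pytest.raises(ValueError):
            estimate_population_uniqueness(hist(1, 2), 1.5)

    def test_zipf_population_oracle(self):
        # brute-force population counting on a skewed 500-value domain
        errors = []
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            p = 1.0 / np.arange(1, 501, dtype=float)
            p /= p.sum()
            population = rng.choice(500, size=10_000, p=p)
            counts = np.bincount(population, minlength=500)
            true_frac = float((counts == 1).sum()) / 10_000
            sample = rng.choice(population, size=1_000, replace=False)
            sc = np.bincount(sample, minlength=500)
            h = EquivalenceClassHistogram(tuple(int(s) for s in sc[sc > 0]))
            est = estimate_population_uniqueness(h, 0.1)
            errors.append(abs(est - true_frac))
        assert np.mean(errors) <= 0.05

    def test_removing_singletons_never_raises_estimate(self):
        rng = np.random.default_rng(33)
        checked = 0
        for _ in range(30):
            sizes = [int(s) for s in rng.integers(1, 8, size=rng.integers(5, 40))]
            if 1 not in sizes:
                sizes.append(1)
            h = EquivalenceClassHistogram(tuple(sizes))
            est = estimate_population_uniqueness(h, 0.2)
            reduced = list(sizes)
            reduced.remove(1)
            if not reduced:
                continue
            est_r = estimate_population_uniqueness(
                EquivalenceClassHistogram(tuple(reduced)), 0.2)
            assert est_r <= est + 1e-9
            checked += 1
        assert checked >= 20


class TestIsSatisfied:
    def test_toy_k3_at_age_star(self):
        assert is_satisfied(apply_scheme(toy8(), (2, 0)), KAnonymity(3))

    def test_toy_k5_at_bottom(self):
        assert not is_satisfied(apply_scheme(toy8(), (0, 0)), KAnonymity(5))

    def test_empty_output_satisfies_uniqueness(self):
        t = suppress_to_satisfy(apply_scheme(toy8(), (0, 0)), KAnonymity(99))
        assert is_satisfied(t, PopulationUniqueness(0.01, 0.1))

    def test_uniqueness_suppression_meets_threshold(self):
        # a table of mostly-unique rows must be pruned until the estimate drops
        import pandas as pd
        from anonlattice import AttributeDefinition, Dataset, Role
        from anonlattice import GeneralizationHierarchy, equivalence_classes
        rng = np.random.default_rng(8)
        values = [str(v) for v in rng.integers(0, 40, size=60)]
        hier = GeneralizationHierarchy(
            "v", tuple((str(v), "*") for v in range(40)))
        ds = Dataset(
            (AttributeDefinition("v", Role.QUASI_IDENTIFYING, hier),),
            pd.DataFrame({"v": values}, dtype=object))
        model = PopulationUniqueness(threshold=0.05, sampling_fraction=0.5)
        t = suppress_to_satisfy(apply_scheme(ds, (0,)), model)
        assert is_satisfied(t, model)
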