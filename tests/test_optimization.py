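"""GA and Nelder-Mead parameter fitting."""

import numpy as np
import pytest

from salif.config import default_params
from salif.optimize import (
    PARAM_NAMES,
    FitnessSpec,
    GAConfig,
    ParamVector,
    SimContext,
    fitness_per_image_ks,
    fitness_sum_ks_z,
    fitness_z_gate_then_ks,
    ga_optimize,
    next_generation,
    nm_optimize,
    simulate_latencies,
)
from salif.stats import LatencySample
from salif.synthetic import random_map_set


@pytest.fixture(scope="module")
def setup():
    lif, wta, noise = default_params()
    maps = random_map_set(6, shape=(12, 12), seed=21)
    ctx = SimContext(maps=maps, base_lif=lif, base_wta=wta)
    defaults = ParamVector.from_bundles(lif, wta, noise)
    lat, _, _ = simulate_latencies(defaults, ctx, seed=0)
    truth = LatencySample(lat + 20.0, "truth")  # shifted target
    return ctx, defaults, truth


class TestParamVector:
    def test_round_trip_bijection(self):
        lif, wta, noise = default_params()
        vec = ParamVector.from_bundles(lif, wta, noise)
        lif2, wta2, noise2 = vec.to_bundles(lif, wta)
        assert (lif2, wta2, noise2) == (lif, wta, noise)
        vec2 = ParamVector.from_bundles(lif2, wta2, noise2)
        np.testing.assert_array_equal(vec.values, vec2.values)

    def test_length_checked(self):
        with pytest.raises(ValueError):
            ParamVector(np.zeros(5))

    def test_names_cover_vector(self):
        assert len(PARAM_NAMES) == 12


class TestFitness:
    def test_identical_sample_zero_fitness(self, setup):
        ctx, defaults, _ = setup
        lat, _, _ = simulate_latencies(defaults, ctx, seed=0)
        f, cmp_ = fitness_sum_ks_z(defaults, LatencySample(lat, "t"), ctx, 0)
        assert f == pytest.approx(0.0, abs=1e-9)
        assert cmp_.D == 0.0

    def test_non_firing_penalized(self, setup):
        ctx, defaults, truth = setup
        dead = ParamVector(defaults.values.copy())
        dead.values[3] = 0.0  # Ginput = 0: no drive, all runs censored
        f, cmp_ = fitness_sum_ks_z(dead, truth, ctx, 0)
        assert f == 1e6 and cmp_ is None

    def test_repeatable_given_seed(self, setup):
        ctx, defaults, truth = setup
        a, _ = fitness_sum_ks_z(defaults, truth, ctx, 42)
        b, _ = fitness_sum_ks_z(defaults, truth, ctx, 42)
        assert a == b

    def test_z_gate_ranking(self):
        # (D, z, p_z)
        evals = [(0.3, 0.5, 0.6), (0.1, 3.0, 0.001),
                 (0.2, 0.1, 0.9), (0.5, 2.0, 0.04)]
        order = fitness_z_gate_then_ks(evals)
        assert order == [2, 0, 3, 1]  # passers by D, then failers by |z|
        all_pass = [(0.3, 0, 0.5), (0.1, 0, 0.5)]
        assert fitness_z_gate_then_ks(all_pass) == [1, 0]
        none_pass = [(0.3, 2.0, 0.01), (0.1, 1.0, 0.01)]
        assert fitness_z_gate_then_ks(none_pass) == [1, 0]

    def test_per_image_single_image_is_plain_d(self, setup):
        ctx, defaults, _ = setup
        lat, ids, _ = simulate_latencies(defaults, ctx, seed=0)
        img = int(ids[0])
        truth_img = {img: LatencySample(lat[ids == img] + 30.0, "t")}
        from salif.stats import ks_two_sample

        f = fitness_per_image_ks(defaults, truth_img, ctx, 0)
        D, _ = ks_two_sample(LatencySample(lat[ids == img], "m"),
                             truth_img[img])
        assert f == pytest.approx(D)

    def test_per_image_additive_over_images(self, setup):
        ctx, defaults, _ = setup
        lat, ids, _ = simulate_latencies(defaults, ctx, seed=0)
        truth = {int(i): LatencySample(lat[ids == i] + 10.0, "t")
                 for i in np.unique(ids)}
        total = fitness_per_image_ks(defaults, truth, ctx, 0)
        parts = sum(fitness_per_image_ks(defaults, {k: v}, ctx, 0)
                    for k, v in truth.items())
        assert total == pytest.approx(parts)


class TestGeneticAlgorithm:
    def test_identity_limit(self, setup):
        """mutation_max = 0 and no resets leave the population (and the
        best vector) at the initial point."""
        ctx, defaults, truth = setup
        cfg = GAConfig(population=6, mutation_max=0.0, reset_count=0,
                       max_generations=3, alpha=0.0, seed=0)
        res = ga_optimize(defaults, truth, ctx, cfg)
        np.testing.assert_array_equal(res.best_params.values, defaults.values)
        assert len(set(res.fitness_trace)) == 1

    def test_reset_rule(self):
        """After a selection step, exactly reset_count contenders equal
        the initial vector."""
        rng = np.random.default_rng(0)
        initial = ParamVector(np.ones(12))
        pop = [ParamVector(np.full(12, 2.0 + i * 0.01)) for i in range(10)]
        cfg = GAConfig(population=10, reset_count=4, seed=0)
        nxt = next_generation(pop, list(range(10)), pop[0], initial, cfg,
                              rng, np.ones(12, bool))
        assert len(nxt) == 10
        n_resets = sum(np.array_equal(v.values, initial.values) for v in nxt)
        assert n_resets == 4

    def test_elite_trace_non_increasing(self, setup):
        ctx, defaults, truth = setup
        cfg = GAConfig(population=10, reset_count=3, max_generations=5,
                       alpha=0.0, seed=1)
        res = ga_optimize(defaults, truth, ctx, cfg)
        assert all(a >= b for a, b in zip(res.fitness_trace,
                                          res.fitness_trace[1:]))
        assert res.best_fitness <= res.fitness_trace[0]

    def test_surrogate_quadratic_descends(self):
        ctx = SimContext(maps=[])
        initial = ParamVector(np.full(12, 5.0))
        obj = lambda v: float(np.sum((v.values - 3.0) ** 2))  # noqa: E731
        cfg = GAConfig(population=20, max_generations=30, alpha=0.0, seed=2)
        res = ga_optimize(initial, None, ctx, cfg, objective=obj)
        assert res.best_fitness < obj(initial)

    def test_z_gate_variant_runs(self, setup):
        """GA selection by the z-gate ranking produces a valid result."""
        ctx, defaults, truth = setup
        cfg = GAConfig(population=8, reset_count=2, max_generations=2,
                       alpha=0.0, seed=3)
        res = ga_optimize(defaults, truth, ctx, cfg,
                          FitnessSpec(variant="z_gate_then_ks"))
        assert np.isfinite(res.best_fitness)
        assert len(res.fitness_trace) == 2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(population=10, reset_count=10)
        with pytest.raises(ValueError):
            GAConfig(mutation_max=1.5)


class TestNelderMead:
    def test_quadratic_surrogate_1d(self):
        """(x - 3)^2 over the one free coordinate: minimizer within
        1e-3 of 3."""
        initial = ParamVector(np.full(12, 1.0))
        mask = np.zeros(12, bool)
        mask[3] = True
        ctx = SimContext(maps=[], free_mask=mask)
        obj = lambda v: float((v.values[3] - 3.0) ** 2)  # noqa: E731
        res = nm_optimize(initial, None, ctx, objective=obj)
        assert res.best_params.values[3] == pytest.approx(3.0, abs=1e-3)
        # non-free coordinates untouched
        assert (res.best_params.values[~mask] == 1.0).all()

    def test_never_worse_than_start(self, setup):
        ctx, defaults, truth = setup
        res = nm_optimize(defaults, truth, ctx, maxiter=60, seed=0)
        f0, _ = fitness_sum_ks_z(defaults, truth, ctx,
                                 int(np.random.SeedSequence(0)
                                     .generate_state(1)[0] % (2**31)))
        assert res.best_fitness <= f0

    def test_deterministic(self, setup):
        ctx, defaults, truth = setup
        a = nm_optimize(defaults, truth, ctx, maxiter=40, seed=5)
        b = nm_optimize(defaults, truth, ctx, maxiter=40, seed=5)
        np.testing.assert_array_equal(a.best_params.values,
                                      b.best_params.values)
        assert a.best_fitness == b.best_fitness
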