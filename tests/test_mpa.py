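"""Optimizer mechanics: step laws, phase structure, memory, convergence."""

import numpy as np
import pytest

from ecgmpa import mpa
from ecgmpa.mpa import (
    EliteMemory,
    MPAParams,
    SearchSpace,
    brownian_steps,
    compute_cf,
    fads_perturb,
    initialize,
    levy_steps,
    memory_save,
    optimize,
    phase_update,
    rastrigin,
    sphere,
)


class ZeroRNG:
    """Stub generator whose draws are all zero (kills every step term)."""

    def standard_normal(self, shape=None):
        return np.zeros(shape if shape is not None else ())

    def uniform(self, low=0.0, high=1.0, size=None):
        return np.zeros(size if size is not None else ())


class TestInitialize:
    def test_degenerate_bounds_collapse_to_point(self):
        space = SearchSpace(lower=[2.0, -1.0], upper=[2.0, -1.0])
        pop = initialize(space, 5, np.random.default_rng(0))
        np.testing.assert_array_equal(pop, np.tile([2.0, -1.0], (5, 1)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_within_bounds_any_seed(self, seed):
        space = SearchSpace(lower=[-3.0, 0.0], upper=[1.0, 10.0])
        pop = initialize(space, 50, np.random.default_rng(seed))
        assert (pop >= space.lower).all() and (pop <= space.upper).all()

    def test_empirical_mean_is_box_center(self):
        space = SearchSpace(lower=[-4.0], upper=[8.0])
        pop = initialize(space, 100_000, np.random.default_rng(3))
        se = (8.0 - (-4.0)) / np.sqrt(12 * 100_000)  # sd of uniform / sqrt(n)
        assert abs(pop.mean() - 2.0) <= 3 * se


class TestCF:
    def test_closed_form_values(self):
        assert compute_cf(0, 100) == 1.0
        assert compute_cf(100, 100) == 0.0
        assert compute_cf(50, 100) == pytest.approx(0.5)

    def test_t_beyond_tmax_rejected(self):
        with pytest.raises(ValueError):
            compute_cf(101, 100)


class TestStepLaws:
    def test_brownian_moments(self):
        draws = brownian_steps((1_000_000,), np.random.default_rng(0))
        assert abs(draws.mean()) < 3e-3
        assert abs(draws.var() - 1.0) < 0.01

    def test_levy_heavier_tailed_than_brownian(self):
        rng = np.random.default_rng(1)
        levy = levy_steps((1_000_000,), 1.5, rng)
        brown = brownian_steps((1_000_000,), rng)
        assert np.mean(np.abs(levy) > 10) > np.mean(np.abs(brown) > 10)
        assert np.mean(np.abs(levy) > 10) > 0

    def test_fixed_seed_reproducible(self):
        a = levy_steps((5, 3), 1.5, np.random.default_rng(7))
        b = levy_steps((5, 3), 1.5, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestPhaseUpdate:
    space = SearchSpace(lower=[-10.0] * 4, upper=[10.0] * 4)

    def _pop_elite(self, n=10):
        rng = np.random.default_rng(0)
        pop = initialize(self.space, n, rng)
        elite = np.tile(pop[0], (n, 1))
        return pop, elite

    def test_zero_draws_leave_phase1_population_unchanged(self):
        pop, elite = self._pop_elite()
        out = phase_update(
            pop, elite, t=0, tmax=30, params=MPAParams(), space=self.space, rng=ZeroRNG()
        )
        np.testing.assert_array_equal(out, pop)

    def test_midphase_splits_population_in_half(self, monkeypatch):
        """At t = tmax/2 the first ceil(n/2) rows move by the Lévy rule
        (additive around their own position) and the rest by the
        Brownian-CF rule (rebuilt from the elite)."""
        pop, elite = self._pop_elite(n=10)
        # kill the Brownian draws: exploitation rows collapse onto the elite
        monkeypatch.setattr(mpa, "brownian_steps", lambda shape, rng: np.zeros(shape))
        out = phase_update(
            pop, elite, t=15, tmax=30, params=MPAParams(), space=self.space,
            rng=np.random.default_rng(2),
        )
        np.testing.assert_array_equal(out[5:], elite[5:])
        assert not np.array_equal(out[:5], elite[:5])

    @pytest.mark.parametrize("t,tmax", [(0, 30), (15, 30), (25, 30)])
    def test_updates_stay_inside_bounds(self, t, tmax):
        pop, elite = self._pop_elite()
        out = phase_update(
            pop, elite, t, tmax, MPAParams(), self.space, np.random.default_rng(3)
        )
        assert (out >= self.space.lower).all() and (out <= self.space.upper).all()


class TestMemorySave:
    def _memory(self, pop, fit):
        _, mem = memory_save(pop, fit, None)
        return mem

    def test_worse_fitness_everywhere_keeps_archive(self):
        pop = np.arange(6.0).reshape(3, 2)
        mem = self._memory(pop, np.array([1.0, 2.0, 3.0]))
        new_pop, mem2 = memory_save(pop + 100, np.array([5.0, 6.0, 7.0]), mem)
        np.testing.assert_array_equal(mem2.positions, pop)
        np.testing.assert_array_equal(new_pop, pop)  # rows restored from archive

    def test_equal_fitness_keeps_archive(self):
        pop = np.arange(6.0).reshape(3, 2)
        mem = self._memory(pop, np.array([1.0, 2.0, 3.0]))
        moved = pop + 1
        _, mem2 = memory_save(moved, np.array([1.0, 2.0, 3.0]), mem)
        np.testing.assert_array_equal(mem2.positions, pop)

    def test_mixed_case_hand_trace(self):
        pop = np.array([[0.0], [1.0], [2.0]])
        mem = self._memory(pop, np.array([3.0, 1.0, 4.0]))
        moved = np.array([[5.0], [6.0], [7.0]])
        new_pop, mem2 = memory_save(moved, np.array([2.0, 9.0, 0.5]), mem)
        # row 0 improved (2<3), row 1 worsened (9>1), row 2 improved (0.5<4)
        np.testing.assert_array_equal(mem2.positions, [[5.0], [1.0], [7.0]])
        np.testing.assert_array_equal(mem2.fitness, [2.0, 1.0, 0.5])
        np.testing.assert_array_equal(new_pop, [[5.0], [1.0], [7.0]])
        assert mem2.top_fitness == 0.5
        np.testing.assert_array_equal(mem2.top_position, [7.0])


class TestFADs:
    space = SearchSpace(lower=[-5.0] * 3, upper=[5.0] * 3)

    def test_disabled_leaves_population_unchanged(self):
        pop = initialize(self.space, 8, np.random.default_rng(0))
        params = MPAParams(fads=0.0, fads_pairwise=False)
        out = fads_perturb(pop, 3, 20, self.space, params, np.random.default_rng(1))
        np.testing.assert_array_equal(out, pop)

    def test_perturbed_rows_stay_inside_bounds(self):
        pop = initialize(self.space, 20, np.random.default_rng(2))
        out = fads_perturb(
            pop, 1, 20, self.space, MPAParams(fads=1.0), np.random.default_rng(3)
        )
        assert (out >= self.space.lower).all() and (out <= self.space.upper).all()

    def test_matches_hand_implementation_at_fads_one(self):
        """Oracle: re-derive the long-jump formula with the same draw order."""
        pop = initialize(self.space, 6, np.random.default_rng(4))
        params = MPAParams(fads=1.0)
        out = fads_perturb(pop, 5, 20, self.space, params, np.random.default_rng(9))

        rng = np.random.default_rng(9)
        n, d = pop.shape
        cf = compute_cf(5, 20)
        jump = rng.uniform(size=n) < 1.0  # all rows jump
        u = rng.uniform(size=(n, d))
        mask = rng.uniform(size=(n, d)) < 1.0
        lo, hi = self.space.lower, self.space.upper
        expected = np.clip(pop + cf * (lo + u * (hi - lo)) * mask, lo, hi)
        assert jump.all()
        np.testing.assert_allclose(out, expected)


class TestOptimize:
    def test_degenerate_space_returns_the_point(self):
        space = SearchSpace(lower=[3.0], upper=[3.0])
        result = optimize(sphere, space, MPAParams(n=2, tmax=1, seed=0))
        np.testing.assert_array_equal(result.best_position, [3.0])
        assert result.best_fitness == 9.0

    def test_trace_nonincreasing_and_bounds_respected(self):
        space = SearchSpace(lower=[-5.12] * 4, upper=[5.12] * 4)
        seen = []

        def audited(x):
            seen.append(x.copy())
            return rastrigin(x)

        result = optimize(audited, space, MPAParams(n=15, tmax=40, seed=5))
        assert np.all(np.diff(result.trace) <= 0)
        positions = np.array(seen)
        assert (positions >= space.lower).all() and (positions <= space.upper).all()
        assert result.evaluations == len(seen)

    def test_sphere_converges(self):
        space = SearchSpace(lower=[-10.0] * 5, upper=[10.0] * 5)
        result = optimize(sphere, space, MPAParams(n=25, tmax=100, seed=0))
        assert result.best_fitness < 1e-2

    def test_seed_reproducibility_and_spread(self):
        space = SearchSpace(lower=[-10.0] * 3, upper=[10.0] * 3)
        a = optimize(sphere, space, MPAParams(n=10, tmax=20, seed=1))
        b = optimize(sphere, space, MPAParams(n=10, tmax=20, seed=1))
        c = optimize(sphere, space, MPAParams(n=10, tmax=20, seed=2))
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.best_fitness == b.best_fitness
        assert not np.array_equal(a.best_position, c.best_position)

    def test_nonfinite_objective_reported_with_position(self):
        space = SearchSpace(lower=[-1.0], upper=[1.0])

        def bad(x):
            return float("nan")

        with pytest.raises(ValueError, match="position"):
            optimize(bad, space, MPAParams(n=3, tmax=2, seed=0))

    def test_beats_random_search_on_quadratics(self):
        """Paired-seed comparison against pure random search at equal budget."""
        space = SearchSpace(lower=[-10.0] * 5, upper=[10.0] * 5)
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            params = MPAParams(n=25, tmax=100, seed=seed)
            res = optimize(sphere, space, params)
            rng = np.random.default_rng(seed)
            draws = space.lower + rng.uniform(
                size=(res.evaluations, space.dim)
            ) * (space.upper - space.lower)
            random_best = np.min(np.sum(draws**2, axis=1))
            wins += res.best_fitness < random_best
        assert wins >= 0.9 * n_seeds

    def test_phase1_as_printed_variant_runs(self):
        space = SearchSpace(lower=[-10.0] * 3, upper=[10.0] * 3)
        result = optimize(
            sphere, space, MPAParams(n=10, tmax=30, seed=0, phase1="levy")
        )
        assert result.best_fitness < 1.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MPAParams(n=1)
        with pytest.raises(ValueError):
            MPAParams(fads=1.5)
        with pytest.raises(ValueError):
            MPAParams(phase1="marche")
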