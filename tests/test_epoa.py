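"""Pelican-optimizer unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epoadl import epoa


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def unit_space(m=2):
    return epoa.SearchSpace(np.zeros(m), np.ones(m))


class TestSearchSpace:
    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            epoa.SearchSpace(np.array([5.0]), np.array([5.0]))

    def test_clip_respects_bounds(self):
        sp = epoa.SearchSpace(np.array([-1.0, 0.0]), np.array([1.0, 2.0]))
        assert sp.contains(sp.clip(np.array([9.0, -9.0])))


class TestLogisticSineMap:
    @pytest.mark.parametrize(
        "z,mu,expected",
        [
            (0.0, 2.0, 0.0),  # both terms vanish
            (0.5, 4.0, 0.0),  # pure logistic hits 1.0, wraps to 0
            (0.3, 2.0, 0.42 + 0.5 * np.sin(0.3 * np.pi)),
        ],
    )
    def test_pointwise_values(self, z, mu, expected):
        assert epoa.logistic_sine_step(z, mu) == pytest.approx(expected, abs=1e-12)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(ValueError):
            epoa.logistic_sine_step(-0.1, 2.0)

    @given(st.floats(0.0, 1.0), st.floats(0.01, 4.0))
    @settings(deadline=None, max_examples=200)
    def test_range_is_half_open_unit_interval(self, z, mu):
        out = epoa.logistic_sine_step(z, mu)
        assert 0.0 <= out < 1.0

    def test_mu_4_reduces_to_logistic_trajectory(self):
        """At mu=4 the sine weight vanishes, so the orbit is the logistic map's."""
        stream = epoa.chaotic_stream(40, 4.0, np.random.default_rng(3), burn_in=10)
        # replicate: same start, iterate the pure logistic map (mod 1)
        z = np.random.default_rng(3).uniform()
        for _ in range(10):
            z = epoa.logistic_step(z, 4.0) % 1.0
        for v in stream:
            z = epoa.logistic_step(z, 4.0) % 1.0
            assert v == pytest.approx(z, abs=1e-12)

    def test_stream_values_in_unit_interval(self):
        stream = epoa.chaotic_stream(500, 2.0, np.random.default_rng(0))
        assert np.all((stream >= 0) & (stream < 1))


class TestInitialization:
    def test_chaotic_positions_equal_raw_stream_on_unit_box(self):
        cfg = epoa.EPOAConfig(pop_size=4, max_iter=1, seed=5)
        rng = np.random.default_rng(11)
        pop = epoa.init_population_chaotic(unit_space(3), cfg, sphere, rng)
        raw = epoa.chaotic_stream(12, cfg.mu, np.random.default_rng(11), cfg.burn_in)
        got = np.concatenate([p.position for p in pop])
        assert np.allclose(got, raw)

    @pytest.mark.parametrize("init", ["chaotic", "uniform"])
    def test_positions_in_bounds_and_reproducible(self, init):
        fn = epoa.init_population_chaotic if init == "chaotic" else epoa.init_population_uniform
        sp = epoa.SearchSpace(np.array([-3.0, 10.0]), np.array([3.0, 20.0]))
        cfg = epoa.EPOAConfig(pop_size=6, max_iter=1, seed=0)
        pop1 = fn(sp, cfg, sphere, np.random.default_rng(1))
        pop2 = fn(sp, cfg, sphere, np.random.default_rng(1))
        for p1, p2 in zip(pop1, pop2):
            assert sp.contains(p1.position)
            assert np.array_equal(p1.position, p2.position)
            assert p1.fitness == sphere(p1.position)


class TestPrey:
    def test_deterministic_and_consistent(self):
        sp = unit_space(2)
        prey1 = epoa.sample_prey(sp, sphere, np.random.default_rng(2))
        prey2 = epoa.sample_prey(sp, sphere, np.random.default_rng(2))
        assert np.array_equal(prey1.position, prey2.position)
        assert prey1.fitness == sphere(prey1.position)

    def test_uniform_moments(self):
        """Per-coordinate mean of many draws sits at the midpoint +/- 3 s.e."""
        sp = epoa.SearchSpace(np.array([2.0, -4.0]), np.array([6.0, 0.0]))
        rng = np.random.default_rng(0)
        draws = np.array(
            [epoa.sample_prey(sp, sphere, rng).position for _ in range(1000)]
        )
        se = (sp.upper - sp.lower) / np.sqrt(12 * 1000)
        mid = (sp.upper + sp.lower) / 2
        assert np.all(np.abs(draws.mean(axis=0) - mid) < 3 * se)


class TestUpdatePhases:
    WIDE = epoa.SearchSpace(np.array([-100.0]), np.array([100.0]))

    def test_phase1_zero_rand_keeps_position(self):
        prey = epoa.Prey(np.array([0.2]), 0.0)
        out = epoa.phase1_update(np.array([1.0]), 5.0, prey, 1, np.zeros(1), self.WIDE)
        assert out == pytest.approx([1.0])

    def test_phase1_approaches_better_prey(self):
        prey = epoa.Prey(np.array([0.2]), 0.0)
        out = epoa.phase1_update(np.array([1.0]), 5.0, prey, 1, np.array([0.5]), self.WIDE)
        assert out == pytest.approx([0.6])  # 1.0 + 0.5*(0.2 - 1.0)

    def test_phase1_retreats_from_worse_prey(self):
        prey = epoa.Prey(np.array([1.0]), 9.0)
        out = epoa.phase1_update(np.array([2.0]), 5.0, prey, 1, np.array([1.0]), self.WIDE)
        assert out == pytest.approx([3.0])  # 2.0 + (2.0 - 1.0)

    def test_phase1_shape_mismatch_errors(self):
        prey = epoa.Prey(np.array([0.2]), 0.0)
        with pytest.raises(ValueError):
            epoa.phase1_update(np.array([1.0, 2.0]), 5.0, prey, 1, np.zeros(1), self.WIDE)

    def test_phase2_last_iteration_keeps_position(self):
        out = epoa.phase2_update(np.array([1.0]), 10, 10, 0.2, np.array([0.9]), self.WIDE)
        assert out == pytest.approx([1.0])

    def test_phase2_centered_rand_keeps_position(self):
        out = epoa.phase2_update(np.array([1.0]), 3, 10, 0.2, np.array([0.5]), self.WIDE)
        assert out == pytest.approx([1.0])

    def test_phase2_preloop_radius(self):
        out = epoa.phase2_update(np.array([1.0]), 0, 10, 0.2, np.array([1.0]), self.WIDE)
        assert out == pytest.approx([1.2])

    def test_phase2_t_beyond_budget_errors(self):
        with pytest.raises(ValueError):
            epoa.phase2_update(np.array([1.0]), 11, 10, 0.2, np.array([0.5]), self.WIDE)

    def test_greedy_accept_strictly_better_only(self):
        cur = epoa.Pelican(np.array([2.0]), 4.0)
        better = epoa.greedy_accept(cur, np.array([1.0]), sphere)
        assert better.fitness == 1.0
        tie = epoa.greedy_accept(cur, np.array([-2.0]), sphere)  # equal fitness
        assert tie is cur
        worse = epoa.greedy_accept(cur, np.array([3.0]), sphere)
        assert worse is cur


class _ZeroFirstRng:
    """normal() returns zeros on the first call, ones afterwards."""

    def __init__(self):
        self.calls = 0

    def normal(self, loc, scale, size):
        self.calls += 1
        return np.zeros(size) if self.calls == 1 else np.ones(size)


class TestLevy:
    def test_mantegna_sigma_closed_form(self):
        assert epoa.levy_sigma_u(1.5) == pytest.approx(0.6965745025576968, abs=1e-12)

    def test_sigma_rejects_out_of_range_beta(self):
        for beta in (0.0, 2.0, -1.0):
            with pytest.raises(ValueError):
                epoa.levy_sigma_u(beta)

    def test_zero_gaussian_numerator_gives_zero_step(self):
        steps = epoa.levy_steps(1.5, _ZeroFirstRng(), 5)
        assert np.all(steps == 0.0)

    def test_tail_index_monte_carlo(self):
        """log-log survival slope of |s| should sit near -beta for beta=1.5."""
        s = np.abs(epoa.levy_steps(1.5, np.random.default_rng(0), 100_000))
        xs = np.logspace(
            np.log10(np.quantile(s, 0.95)), np.log10(np.quantile(s, 0.999)), 15
        )
        surv = np.array([(s > x).mean() for x in xs])
        slope = np.polyfit(np.log(xs), np.log(surv), 1)[0]
        assert -1.9 <= slope <= -1.1

    def test_jump_from_best_keeps_position(self):
        sp = unit_space(2)
        pel = epoa.Pelican(np.array([0.4, 0.6]), sphere(np.array([0.4, 0.6])))
        out = epoa.levy_jump(pel, pel.position, 1.5, np.random.default_rng(0), sphere, sp)
        assert np.array_equal(out.position, pel.position)

    def test_jump_scalar_arithmetic(self, monkeypatch):
        monkeypatch.setattr(epoa, "levy_steps", lambda beta, rng, size: np.ones(size))
        sp = epoa.SearchSpace(np.array([-10.0]), np.array([10.0]))

        def decreasing(x):  # any candidate further out is better
            return -float(x[0])

        pel = epoa.Pelican(np.array([2.0]), decreasing(np.array([2.0])))
        out = epoa.levy_jump(pel, np.array([1.0]), 1.5, None, decreasing, sp)
        assert out.position[0] == pytest.approx(2.01)  # 2 + 0.01*1*(2-1)

    def test_worse_jump_rejected(self, monkeypatch):
        monkeypatch.setattr(epoa, "levy_steps", lambda beta, rng, size: np.ones(size))
        sp = epoa.SearchSpace(np.array([-10.0]), np.array([10.0]))
        pel = epoa.Pelican(np.array([2.0]), sphere(np.array([2.0])))
        out = epoa.levy_jump(pel, np.array([1.0]), 1.5, None, sphere, sp)
        assert out is pel


class TestOptimize:
    def test_sphere_convergence(self):
        sp = epoa.SearchSpace(np.full(5, -5.0), np.full(5, 5.0))
        res = epoa.optimize(sphere, sp, epoa.EPOAConfig(pop_size=30, max_iter=200, seed=1))
        assert res.best_fitness <= 1e-2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trace_monotone_and_in_bounds(self, seed):
        sp = epoa.SearchSpace(np.array([-2.0, 1.0]), np.array([2.0, 3.0]))

        def rastrigin_like(x):
            return float(np.sum(x**2 - np.cos(3 * x)) + 2)

        cfg = epoa.EPOAConfig(pop_size=8, max_iter=30, seed=seed)
        res = epoa.optimize(rastrigin_like, sp, cfg)
        assert np.all(np.diff(res.trace) <= 0)
        assert res.best_fitness == res.trace[-1]
        assert sp.contains(res.best_position)

    def test_same_seed_same_result(self):
        sp = unit_space(3)
        cfg = epoa.EPOAConfig(pop_size=6, max_iter=15, seed=9)
        r1 = epoa.optimize(sphere, sp, cfg)
        r2 = epoa.optimize(sphere, sp, cfg)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert np.array_equal(r1.trace, r2.trace)

    def test_ablation_flags_control_evaluation_count(self):
        """Enhancements off -> baseline loop: N + T*(1 + 2N) evaluations;
        Lévy on adds one candidate evaluation per pelican per iteration."""
        sp = unit_space(2)
        base = dict(pop_size=4, max_iter=6, seed=0)
        off = epoa.optimize(
            sphere, sp, epoa.EPOAConfig(**base, chaotic_init=False, levy_jumps=False)
        )
        on = epoa.optimize(sphere, sp, epoa.EPOAConfig(**base))
        N, T = base["pop_size"], base["max_iter"]
        assert off.evaluations == N + T * (1 + 2 * N)
        assert on.evaluations == N + T * (1 + 3 * N)

    def test_baseline_variant_is_reproducible(self):
        sp = unit_space(2)
        cfg = epoa.EPOAConfig(pop_size=5, max_iter=10, seed=3, chaotic_init=False, levy_jumps=False)
        r1 = epoa.optimize(sphere, sp, cfg)
        r2 = epoa.optimize(sphere, sp, cfg)
        assert np.array_equal(r1.trace, r2.trace)
        assert np.all(np.diff(r1.trace) <= 0)

    def test_median_final_fitness_2d_sphere(self):
        """Smoke-level convergence: 2-D sphere, N=30, T=100, 20 seeds."""
        sp = epoa.SearchSpace(np.full(2, -5.0), np.full(2, 5.0))
        finals = [
            epoa.optimize(
                sphere, sp, epoa.EPOAConfig(pop_size=30, max_iter=100, seed=s)
            ).best_fitness
            for s in range(20)
        ]
        assert np.median(finals) <= 1e-1

    def test_objective_failure_is_wrapped_with_context(self):
        def bad(x):
            raise RuntimeError("boom")

        with pytest.raises(epoa.ObjectiveError):
            epoa.optimize(bad, unit_space(1), epoa.EPOAConfig(pop_size=2, max_iter=1, seed=0))

    def test_trace_csv_export(self, tmp_path):
        res = epoa.optimize(
            sphere, unit_space(2), epoa.EPOAConfig(pop_size=4, max_iter=5, seed=0)
        )
        path = tmp_path / "trace.csv"
        epoa.save_trace(res, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "iteration,best_fitness,evaluations"
        assert len(lines) == 6
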