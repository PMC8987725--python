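"""PSO and time-factor bat algorithm: analytic forms, step oracles, runs."""

import math

import numpy as np
import pytest

from cropweed import optimizers as opt


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def shifted_sphere(x):
    return float(np.sum((np.asarray(x) - 3.0) ** 2))


class TestAnalyticForms:
    def test_inertia_weight_endpoints_and_linearity(self):
        cfg = opt.PSOConfig()
        assert opt.inertia_weight(0, cfg) == pytest.approx(1.2)
        assert opt.inertia_weight(20, cfg) == pytest.approx(0.8)
        assert opt.inertia_weight(10, cfg) == pytest.approx(1.0)
        # affine in t
        vals = [opt.inertia_weight(t, cfg) for t in range(21)]
        diffs = np.diff(vals)
        assert np.allclose(diffs, diffs[0])
        with pytest.raises(ValueError):
            opt.inertia_weight(21, cfg)

    def test_time_factor_endpoints_midpoint_and_monotone_decrease(self):
        assert opt.time_factor(0, 20) == pytest.approx(2.0)
        assert opt.time_factor(20, 20) == pytest.approx(1.0)
        assert opt.time_factor(10, 20) == pytest.approx(1.0 + math.sin(math.pi / 4))
        vals = [opt.time_factor(t, 20) for t in range(21)]
        assert all(1.0 <= v <= 2.0 for v in vals)
        assert all(a > b for a, b in zip(vals, vals[1:]))
        with pytest.raises(ValueError):
            opt.time_factor(-1, 20)

    def test_pulse_rate_ramps_toward_r0_and_loudness_decays(self):
        cfg = opt.BAConfig()
        state = opt.init_ba_state(
            opt.SearchSpace(dimension=2), cfg, sphere, np.random.default_rng(0)
        )
        state.loudness[:] = 0.1
        opt.pulse_loudness_update(0, state, cfg, t=1)
        assert state.pulse_rates[0] == pytest.approx(0.85 * (1 - math.exp(-0.9)))
        assert state.loudness[0] == pytest.approx(0.09)
        # monotone toward the 0.85 ceiling
        rs = [0.85 * (1 - math.exp(-0.9 * t)) for t in (1, 2, 5, 10)]
        assert all(a < b for a, b in zip(rs, rs[1:])) and rs[-1] < 0.85
        assert 0.85 * (1 - math.exp(-0.9 * 50)) == pytest.approx(0.85, abs=1e-9)


class _ConstantRng:
    """Returns a fixed value for every uniform draw; zeros for normals."""

    def __init__(self, value):
        self.value = value

    def random(self, shape=None):
        return self.value if shape is None else np.full(shape, self.value)

    def standard_normal(self, n):
        return np.zeros(n)


class TestPsoStep:
    def _single_particle_state(self, x, v, fitness_fn):
        x = np.asarray(x, float)[None, :]
        f = np.array([fitness_fn(x[0])])
        return opt.PSOState(
            positions=x.copy(), velocities=np.asarray(v, float)[None, :],
            personal_best=x.copy(), personal_best_fitness=f.copy(),
            global_best=x[0].copy(), global_best_fitness=float(f[0]),
        )

    def test_pure_inertia_advances_position_by_velocity(self):
        cfg = opt.PSOConfig(c1=0.0, c2=0.0, omega_max=1.0, omega_min=1.0)
        space = opt.SearchSpace([-10, -10], [10, 10])
        state = self._single_particle_state([1.0, 1.0], [0.3, -0.1], sphere)
        out = opt.pso_step(state, cfg, space, sphere, _ConstantRng(0.5))
        assert np.allclose(out.positions[0], [1.3, 0.9])

    def test_attraction_vanishes_at_the_shared_best(self):
        cfg = opt.PSOConfig()
        space = opt.SearchSpace([-10, -10], [10, 10])
        state = self._single_particle_state([2.0, -1.0], [0.5, 0.5], sphere)
        out = opt.pso_step(state, cfg, space, sphere, _ConstantRng(0.9))
        omega = opt.inertia_weight(0, cfg)
        assert np.allclose(out.velocities[0], omega * np.array([0.5, 0.5]))

    def test_three_step_trace_matches_hand_computed_oracle(self):
        """Literal velocity/position/inertia recursion with r1 = r2 = 0.5."""
        cfg = opt.PSOConfig(maxiter=20)
        space = opt.SearchSpace([-100, -100], [100, 100])
        x = np.array([4.0, -3.0])
        v = np.array([0.5, 0.5])
        state = self._single_particle_state(x, v, sphere)
        rng = _ConstantRng(0.5)

        # independent oracle: the update equations applied directly
        ox, ov = x.copy(), v.copy()
        op_best, op_bf = x.copy(), sphere(x)
        og_best, og_bf = x.copy(), sphere(x)
        for t in range(3):
            omega = 0.8 + (1.2 - 0.8) * (20 - t) / 20
            ov = omega * ov + 2 * 0.5 * (op_best - ox) + 2 * 0.5 * (og_best - ox)
            ov = np.clip(ov, -2, 2)
            ox = np.clip(ox + ov, -100, 100)
            fx = sphere(ox)
            if fx < op_bf:
                op_best, op_bf = ox.copy(), fx
            if fx < og_bf:
                og_best, og_bf = ox.copy(), fx

        for _ in range(3):
            state = opt.pso_step(state, cfg, space, sphere, rng)
        assert np.allclose(state.positions[0], ox, atol=1e-12)
        assert np.allclose(state.velocities[0], ov, atol=1e-12)
        assert state.global_best_fitness == pytest.approx(og_bf, abs=1e-12)

    def test_velocities_respect_clamp_and_positions_stay_in_box(self):
        cfg = opt.PSOConfig()
        space = opt.SearchSpace([0, 0], [15, 15])
        rng = np.random.default_rng(3)
        state = opt.init_pso_state(space, cfg, shifted_sphere, rng)
        for _ in range(5):
            state = opt.pso_step(state, cfg, space, shifted_sphere, rng)
            assert np.all(np.abs(state.velocities) <= cfg.v_max + 1e-12)
            assert np.all(state.positions >= space.lower - 1e-12)
            assert np.all(state.positions <= space.upper + 1e-12)


class _ScriptedRng:
    """Replays scripted uniform and normal draws in order."""

    def __init__(self, uniforms, normals):
        self.uniforms = list(uniforms)
        self.normals = list(normals)

    def random(self, shape=None):
        assert shape is None
        return self.uniforms.pop(0)

    def standard_normal(self, n):
        return np.asarray(self.normals.pop(0), float)


class TestBatStep:
    def test_velocity_unchanged_when_bat_sits_on_the_best(self):
        cfg = opt.BAConfig(m=1)
        space = opt.SearchSpace([-10, -10], [10, 10])
        state = opt.init_ba_state(space, cfg, sphere, np.random.default_rng(0))
        state.positions[0] = state.global_best.copy()
        state.pulse_rates[:] = 1.0  # force the velocity branch
        v_before = state.velocities.copy()
        out = opt.bat_step(state, cfg, space, sphere, _ConstantRng(0.99))
        assert np.allclose(out.velocities, v_before)

    def test_frequencies_span_the_configured_band(self):
        cfg = opt.BAConfig()
        rng = np.random.default_rng(0)
        u = rng.random(10_000)
        freqs = cfg.f_min + (cfg.f_max - cfg.f_min) * u
        assert freqs.min() >= -1.0 and freqs.max() <= 1.0
        assert freqs.min() < -0.99 and freqs.max() > 0.99

    def test_printed_frequency_form_is_degenerate_with_default_band(self):
        cfg = opt.BAConfig(printed_frequency_form=True)
        span = cfg.f_max + cfg.f_min
        assert span == 0.0  # every frequency collapses to f_min

    def test_two_step_single_bat_trace_matches_hand_oracle(self):
        """Scripted draws through frequency/velocity/time-factor updates."""
        cfg = opt.BAConfig(m=1, maxiter=20)
        space = opt.SearchSpace([-50, -50], [50, 50])
        x0 = np.array([4.0, -2.0])
        best0 = np.array([1.0, 1.0])

        state = opt.BAState(
            positions=x0[None, :].copy(), velocities=np.zeros((1, 2)),
            fitness=np.array([sphere(x0)]), pulse_rates=np.array([0.5]),
            loudness=np.array([0.1]), global_best=best0.copy(),
            global_best_fitness=sphere(best0),
        )
        # step 1: velocity branch (u_branch < r), accepted (u_accept < A)
        # step 2: walk branch (u_branch > r), not accepted
        uniforms = [0.75, 0.40, 0.05, 0.25, 0.90, 0.50]
        normals = [[1.0, -1.0], [0.5, 2.0]]
        rng = _ScriptedRng(list(uniforms), [np.array(n) for n in normals])

        # oracle
        ox, ov = x0.copy(), np.zeros(2)
        obest, obf = best0.copy(), sphere(best0)
        ofit = sphere(x0)
        r, a = 0.5, 0.1
        ur = list(uniforms)
        for t in (1, 2):
            beta = 1 + math.sin(math.pi / 2 - math.pi * t / 40)
            f_i = -1 + 2 * ur.pop(0)
            ov = np.clip(ov + (ox - obest) * f_i, -100, 100)
            cand = ox + beta * ov
            u_branch = ur.pop(0)
            noise = np.array(normals[t - 1])
            if u_branch > r:
                cand = obest + a * noise
            cand = np.clip(cand, -50, 50)
            fc = sphere(cand)
            u_accept = ur.pop(0)
            if fc < ofit and u_accept < a:
                ox, ofit = cand.copy(), fc
                r = 0.85 * (1 - math.exp(-0.9 * t))
                a = 0.9 * a
            if fc < obf:
                obest, obf = cand.copy(), fc

        for _ in range(2):
            state = opt.bat_step(state, cfg, space, sphere, rng)
        assert np.allclose(state.positions[0], ox, atol=1e-12)
        assert np.allclose(state.velocities[0], ov, atol=1e-12)
        assert np.allclose(state.global_best, obest, atol=1e-12)
        assert state.pulse_rates[0] == pytest.approx(r, abs=1e-12)
        assert state.loudness[0] == pytest.approx(a, abs=1e-12)

    def test_time_factor_widens_first_iteration_moves(self):
        """Mean first-move norm with beta(t) strictly exceeds beta == 1."""

        def mean_first_disp(constant_beta):
            norms = []
            for seed in range(100):
                cfg = opt.BAConfig()
                space = opt.SearchSpace([0, 0], [15, 15])
                rng = np.random.default_rng(seed)
                state = opt.init_ba_state(space, cfg, shifted_sphere, rng)
                before = state.positions.copy()
                state = opt.bat_step(state, cfg, space, shifted_sphere, rng,
                                     constant_beta=constant_beta)
                # proposals that were rejected leave the position unchanged;
                # measure realized displacement of the whole population
                norms.append(np.linalg.norm(state.positions - before, axis=1).mean())
            return np.mean(norms)

        assert mean_first_disp(False) > mean_first_disp(True)


class TestRunOptimizer:
    @pytest.mark.parametrize("algorithm", ["pso", "ba"])
    def test_constant_objective_returns_the_constant(self, algorithm):
        space = opt.SearchSpace([0, 0], [15, 15])
        res = opt.run_optimizer(algorithm, space, None, lambda x: 7.0, seed=0)
        assert res.best_fitness == 7.0
        assert np.all(res.best_position >= 0) and np.all(res.best_position <= 15)

    @pytest.mark.parametrize("algorithm", ["pso", "ba"])
    def test_history_non_increasing_and_full_length(self, algorithm):
        space = opt.SearchSpace([0, 0], [15, 15])
        res = opt.run_optimizer(algorithm, space, None, shifted_sphere, seed=1)
        assert len(res.history) == 20
        assert np.all(np.diff(res.history) <= 0)

    @pytest.mark.parametrize("algorithm", ["pso", "ba"])
    def test_same_seed_reproduces_the_run(self, algorithm):
        space = opt.SearchSpace([0, 0], [15, 15])
        a = opt.run_optimizer(algorithm, space, None, shifted_sphere, seed=9)
        b = opt.run_optimizer(algorithm, space, None, shifted_sphere, seed=9)
        assert np.array_equal(a.history, b.history)
        assert np.array_equal(a.best_position, b.best_position)

    @pytest.mark.parametrize("algorithm", ["pso", "ba"])
    def test_sphere_convergence_in_at_least_nine_of_ten_seeds(self, algorithm):
        space = opt.SearchSpace([0, 0], [15, 15])
        wins = sum(
            opt.run_optimizer(algorithm, space, None, shifted_sphere, seed=s
                              ).best_fitness < 0.1
            for s in range(10)
        )
        assert wins >= 9

    def test_failing_evaluator_aborts_with_agent_diagnostic(self):
        space = opt.SearchSpace([0, 0], [15, 15])

        def broken(x):
            raise ZeroDivisionError("boom")

        with pytest.raises(RuntimeError, match="agent"):
            opt.run_optimizer("pso", space, None, broken, seed=0)


class TestConsolidateRuns:
    def test_reference_run_pairs_consolidate_to_integer_averages(self):
        assert opt.consolidate_runs(
            [(10.2354, 7.6387), (6.3334, 9.4124)]) == (8, 8)
        assert opt.consolidate_runs(
            [(6.1143, 9.7588), (2.2756, 14.0331)]) == (4, 12)

    def test_identity_on_integer_single_run(self):
        assert opt.consolidate_runs([(3.0, 5.0)]) == (3, 5)

    def test_half_to_even_rounding_both_stages(self):
        # 2.5 -> 2 and 3.5 -> 4 at the per-run stage
        assert opt.consolidate_runs([(2.5, 3.5)]) == (2, 4)
        # averaging stage: (2 + 3)/2 = 2.5 -> 2
        assert opt.consolidate_runs([(2.0, 1.0), (3.0, 1.0)]) == (2, 1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            opt.consolidate_runs([])
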