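"""Target-state generation: integration, explicit curves, normalization."""

import numpy as np
import pytest

from rcmem.dynamics import (
    SYSTEMS,
    DivergenceError,
    SystemSpec,
    Trajectory,
    _fourier_design,
    average_period,
    bifurcation_library,
    denormalize,
    fourier_attractor,
    integrate_batch,
    integrate_system,
    lissajous,
    normalize,
)


class TestIntegration:
    def test_unknown_system_rejected(self):
        with pytest.raises(ValueError, match="unknown system_id"):
            SystemSpec("not_a_system")

    def test_foodchain_origin_is_fixed_point(self):
        # all three growth rates vanish at (R, C, P) = (0, 0, 0)
        spec = SystemSpec("foodchain")
        out = integrate_batch(spec, 50, np.zeros(3))
        assert np.all(out == 0.0)

    def test_deterministic_given_seed(self):
        spec = SystemSpec("rossler")
        a = integrate_system(spec, 500, seed=42)
        b = integrate_system(spec, 500, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_sampling_matches_fine_step_reference(self):
        # dt=0.01 sampled every 10 steps vs a 10x finer integration of the
        # same initial condition, compared at the shared sample times
        x0 = np.array([0.05, 0.05, 0.05])
        coarse = integrate_batch(SystemSpec("sprott_b", integrate_dt=0.01, sample_every=10), 101, x0)
        fine = integrate_batch(SystemSpec("sprott_b", integrate_dt=0.001, sample_every=100), 101, x0)
        assert np.max(np.abs(coarse - fine)) < 1e-4

    def test_divergence_reports_step(self):
        # overly large RK4 step makes the Lorenz integration blow up
        spec = SystemSpec("lorenz", integrate_dt=0.5, sample_every=1, transient_steps=0)
        with pytest.raises(DivergenceError):
            integrate_system(spec, 2000, seed=0)

    def test_halving_dt_barely_moves_periodic_orbit(self):
        # integration convergence on a stable limit cycle over ~10 cycles
        x0 = np.array([0.05, 0.05, 0.05])
        base = dict(params={"a": 0.25}, sample_every=10, transient_steps=0)
        a = integrate_batch(SystemSpec("sprott_f", integrate_dt=0.01, **base), 600, x0)
        b = integrate_batch(
            SystemSpec("sprott_f", integrate_dt=0.005, sample_every=20, params={"a": 0.25}), 600, x0
        )
        assert np.max(np.abs(a - b)) < 1e-5

    def test_time_scale_speeds_up_flow(self):
        spec1 = SystemSpec("rossler", transient_steps=500)
        spec2 = SystemSpec("rossler", transient_steps=500, time_scale=2.0)
        p1 = average_period(integrate_system(spec1, 4000, seed=1), 0)
        p2 = average_period(integrate_system(spec2, 4000, seed=1), 0)
        assert p2 == pytest.approx(p1 / 2, rel=0.1)


class TestNormalize:
    def test_zero_mean_unit_std(self):
        rng = np.random.default_rng(0)
        traj = Trajectory(rng.uniform(-3, 5, size=(500, 4)))
        out = normalize(traj)
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(out.values.std(axis=0) - 1) < 1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        once = normalize(Trajectory(rng.standard_normal((300, 2)) * 7 + 3))
        twice = normalize(once)
        assert np.max(np.abs(once.values - twice.values)) < 1e-10

    def test_two_point_population_convention(self):
        out = normalize(Trajectory(np.array([[0.0], [2.0]])))
        assert np.allclose(out.values[:, 0], [-1.0, 1.0])

    def test_constant_dimension_named_in_error(self):
        vals = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            normalize(Trajectory(vals))

    def test_denormalize_round_trip(self):
        rng = np.random.default_rng(2)
        traj = Trajectory(rng.standard_normal((200, 3)) * 4 - 2)
        back = denormalize(normalize(traj))
        assert np.allclose(back.values, traj.values, atol=1e-12)


class TestFourierAttractor:
    def test_exact_discrete_periodicity(self):
        traj = fourier_attractor(seed=3, dims=3, n_steps=450)
        assert np.allclose(traj.values[:250], traj.values[200:450], atol=1e-9)

    def test_deterministic(self):
        a = fourier_attractor(seed=9, dims=3)
        b = fourier_attractor(seed=9, dims=3)
        assert np.array_equal(a.values, b.values)

    def test_interpolates_control_points_like_normal_equations(self):
        # re-derive the fit independently: with k <= 9 points and 9 Fourier
        # coefficients the minimum-norm LS solution interpolates; solving the
        # dual normal equations A^T (A A^T)^-1 y gives the same curve
        rng = np.random.default_rng(7)
        phases = rng.uniform(0, 200, size=4)
        targets = rng.uniform(-1, 1, size=4)
        A = _fourier_design(phases, 4, 200)
        coef_dual = A.T @ np.linalg.solve(A @ A.T, targets)
        coef_lstsq = np.linalg.lstsq(A, targets, rcond=None)[0]
        assert np.allclose(A @ coef_lstsq, targets, atol=1e-8)
        assert np.allclose(coef_dual, coef_lstsq, atol=1e-8)

    def test_rejects_too_short_period(self):
        with pytest.raises(ValueError):
            fourier_attractor(seed=0, period_steps=10, order=4)


class TestAveragePeriod:
    def test_sine_period(self):
        t = np.arange(2000)
        traj = Trajectory(np.sin(2 * np.pi * t / 50.0))
        assert average_period(traj) == pytest.approx(50, abs=1)

    def test_matches_bruteforce_scan(self, lorenz_coarse):
        x = lorenz_coarse.values[:5000, 0]
        # independent brute-force scan over strict three-point maxima
        maxima = [i for i in range(1, len(x) - 1) if x[i - 1] < x[i] > x[i + 1]]
        expected = np.mean(np.diff(maxima))
        got = average_period(lorenz_coarse.segment(0, 5000), 0)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_monotone_series_errors(self):
        with pytest.raises(ValueError):
            average_period(Trajectory(np.arange(100.0)))


class TestLissajous:
    def test_periodicity_and_metadata(self):
        traj = lissajous(400, period_steps=40)
        assert traj.is_periodic and traj.period_steps == 40
        assert np.allclose(traj.values[:360], traj.values[40:400], atol=1e-12)


class TestBifurcationLibrary:
    def test_structure_indices_and_order(self):
        lib = bifurcation_library(n_states=5, n_steps=400, transient_time=500.0, seed=1)
        assert lib.K == 5
        codes = lib.coding.codes[:, 0]
        assert codes[0] == -2.5 and codes[-1] == 2.5
        assert np.all(np.diff(codes) > 0)  # strictly increasing with K_f
        diffs = np.diff(codes)
        assert np.allclose(diffs, diffs[0])  # evenly separated
        assert all(t.dt == 1.0 for t in lib.trajectories)

    def test_two_states_hit_endpoints(self):
        lib = bifurcation_library(n_states=2, n_steps=300, transient_time=300.0)
        assert np.allclose(lib.coding.codes[:, 0], [-2.5, 2.5])
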