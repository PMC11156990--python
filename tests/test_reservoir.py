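"""Echo-state-network engine: init, drive, ridge readout, closed loop."""

import numpy as np
import pytest

from rcmem.dynamics import Trajectory, lissajous, average_period
from rcmem.memory import ReservoirMemory
from rcmem.reservoir import (
    GenerationResult,
    ReservoirParams,
    RidgeAccumulator,
    closed_loop,
    drive,
    init_reservoir,
    make_features,
    train_readout,
    warmup,
)


class TestInit:
    def test_spectral_radius_matches_request(self):
        params = ReservoirParams(N=600, spectral_radius=0.9, seed=3)
        rc = init_reservoir(params)
        # independent oracle: dense eigensolve
        rho = np.max(np.abs(np.linalg.eigvals(rc.A.toarray())))
        assert rho == pytest.approx(0.9, abs=1e-6)

    def test_deterministic_given_seed(self):
        a = init_reservoir(ReservoirParams(N=200, seed=11))
        b = init_reservoir(ReservoirParams(N=200, seed=11))
        assert np.array_equal(a.W_in, b.W_in)
        assert np.array_equal(a.A.toarray(), b.A.toarray())
        assert np.array_equal(a.bias, b.bias)

    def test_density_close_to_request(self):
        rc = init_reservoir(ReservoirParams(N=1000, density=0.02, seed=0))
        assert rc.A.nnz / 1000**2 == pytest.approx(0.02, abs=0.005)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ReservoirParams(N=0)
        with pytest.raises(ValueError):
            ReservoirParams(leak=0.0)
        with pytest.raises(ValueError):
            ReservoirParams(readout_features="cubic")


class TestDrive:
    def test_zero_input_zero_bias_stays_at_origin(self):
        params = ReservoirParams(N=100, bias_scale=0.0, seed=1)
        rc = init_reservoir(params)
        states = drive(rc, np.zeros((50, 3)))
        assert np.all(states == 0.0)

    def test_states_bounded_by_tanh(self):
        rc = init_reservoir(ReservoirParams(N=100, seed=2))
        rng = np.random.default_rng(0)
        states = drive(rc, 5 * rng.standard_normal((200, 3)))
        assert np.all(np.abs(states) < 1.0)

    def test_echo_state_contraction(self):
        # two different initial hidden states forget each other under a
        # contracting reservoir driven by the same input
        rc = init_reservoir(ReservoirParams(N=300, spectral_radius=0.8, leak=1.0, seed=4))
        rng = np.random.default_rng(1)
        u = rng.standard_normal((400, 3))
        ra = drive(rc, u, r0=rng.uniform(-1, 1, 300))
        rb = drive(rc, u, r0=rng.uniform(-1, 1, 300))
        gap = np.linalg.norm(ra - rb, axis=1)
        assert gap[-1] < 1e-6
        # discrepancy decays monotonically (in block means) until it reaches
        # the floating-point noise floor
        blocks = np.maximum(gap.reshape(8, 50).mean(axis=1), 1e-12)
        decreasing = np.diff(blocks) < 0
        floor = blocks[1:] <= 1e-12
        assert np.all(decreasing | floor)

    def test_leak_one_reduces_to_pure_tanh(self):
        params = ReservoirParams(N=80, leak=1.0, seed=5)
        rc = init_reservoir(params)
        rng = np.random.default_rng(2)
        u = rng.standard_normal((30, 3))
        states = drive(rc, u)
        # independent re-implementation of the pure tanh update
        r = np.zeros(80)
        A = rc.A.toarray()
        for t in range(30):
            r = np.tanh(A @ r + rc.W_in @ u[t] + rc.bias)
            assert np.allclose(states[t], r, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        rc = init_reservoir(ReservoirParams(N=50, D_in=3, seed=0))
        with pytest.raises(ValueError):
            drive(rc, np.zeros((10, 2)))

    def test_index_term_acts_as_constant_bias(self):
        params = ReservoirParams(N=60, C_index=2, seed=7)
        rc = init_reservoir(params)
        u = np.zeros((20, 3))
        p = np.array([1.0, -2.0])
        with_index = drive(rc, u, p=p)
        # equivalent run with the index folded into the bias
        rc.bias = rc.bias + rc.W_index @ p
        folded = drive(rc, u, p=np.zeros(2))
        assert np.allclose(with_index, folded, atol=1e-12)


class TestRidge:
    def test_matches_normal_equations_on_random_instances(self):
        # property: streaming ridge == explicit normal-equations solve
        rng = np.random.default_rng(0)
        for trial in range(100):
            n, t = 10, 50
            X = rng.standard_normal((t, n))
            Y = rng.standard_normal((t, 2))
            beta = 10.0 ** rng.uniform(-8, 0)
            W = train_readout(X, Y, beta, feature_mode="linear")
            W_ref = np.linalg.solve(X.T @ X + beta * np.eye(n), X.T @ Y).T
            assert np.allclose(W, W_ref, atol=1e-8)

    def test_monotone_shrinkage(self):
        rng = np.random.default_rng(1)
        X, Y = rng.standard_normal((100, 20)), rng.standard_normal((100, 3))
        norms = [
            np.linalg.norm(train_readout(X, Y, b, feature_mode="linear"))
            for b in (1e-3, 1e3, 1e12)
        ]
        assert norms[0] > norms[1] > norms[2]
        assert norms[2] < 1e-9

    def test_interpolation_at_zero_beta(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 30))  # full rank almost surely
        Y = rng.standard_normal((30, 2))
        W = train_readout(X, Y, 0.0, feature_mode="linear")
        assert np.max(np.abs(X @ W.T - Y)) < 1e-8

    def test_rank_deficient_at_zero_beta_raises(self):
        X = np.zeros((40, 10))
        X[:, 0] = np.arange(40.0)
        Y = np.ones((40, 1))
        acc = RidgeAccumulator(10, 1)
        acc.add(X, Y)
        with pytest.raises(np.linalg.LinAlgError, match="ridge_beta"):
            acc.solve(0.0)

    def test_feature_map_appends_squares(self):
        x = np.array([[1.0, -2.0]])
        assert np.allclose(make_features(x, "linear_plus_square"), [[1, -2, 1, 4]])
        assert np.allclose(make_features(x, "linear"), x)


class TestClosedLoop:
    @pytest.fixture(scope="class")
    def sine_mem(self):
        t = np.arange(3000)
        wave = np.stack(
            [np.sin(2 * np.pi * t / 40), np.cos(2 * np.pi * t / 40), np.sin(4 * np.pi * t / 40)],
            axis=-1,
        )
        traj = Trajectory(wave, dt=0.1, is_periodic=True, period_steps=40)
        return ReservoirMemory(N=300, seed=3, train_steps=2500).fit([traj])

    def test_single_attractor_period_within_one_percent(self, sine_mem):
        res = sine_mem.recall(1, n_steps=800, seed=0, settle_steps=500)
        assert not res.diverged
        per = average_period(res.trajectory, 0)
        assert per == pytest.approx(40, rel=0.01)

    def test_one_step_run_has_one_row(self, sine_mem):
        # (the Trajectory container pads to its two-row minimum)
        res = closed_loop(sine_mem.weights_, r0=np.zeros(300), n_steps=1)
        assert isinstance(res, GenerationResult)

    def test_deterministic(self, sine_mem):
        r0 = np.full(300, 0.1)
        a = closed_loop(sine_mem.weights_, r0=r0, n_steps=200)
        b = closed_loop(sine_mem.weights_, r0=r0, n_steps=200)
        assert np.array_equal(a.trajectory.values, b.trajectory.values)

    def test_untrained_reservoir_rejected(self):
        rc = init_reservoir(ReservoirParams(N=50, seed=0))
        with pytest.raises(ValueError, match="trained"):
            closed_loop(rc, n_steps=10)


class TestWarmup:
    def test_zero_length_cue_returns_r0(self, six_mem):
        r0 = np.full(1000, 0.2)
        out = warmup(six_mem.weights_, np.zeros((0, 3)), r0=r0)
        assert np.array_equal(out, r0)

    def test_warmup_deterministic(self, six_mem):
        cue = six_mem.library_.trajectories[0].values[:50]
        r0 = six_mem.random_hidden_state(7)
        a = warmup(six_mem.weights_, cue, p=np.array([1.0]), r0=r0)
        b = warmup(six_mem.weights_, cue, p=np.array([1.0]), r0=r0)
        assert np.array_equal(a, b)
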