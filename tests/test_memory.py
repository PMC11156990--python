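"""Indexed (location-addressable) memory: training, recall, switching."""

import numpy as np
import pytest

from rcmem.coding import AttractorLibrary
from rcmem.dynamics import Trajectory, average_period
from rcmem.memory import ReservoirMemory, train_indexfree, train_separate_readouts


def _two_wave_library(coding="scalar"):
    t = np.arange(3000)
    w1 = np.stack(
        [np.sin(2 * np.pi * t / 40), np.cos(2 * np.pi * t / 40), np.sin(4 * np.pi * t / 40)],
        axis=-1,
    )
    w2 = np.stack(
        [np.sin(2 * np.pi * t / 60 + 1.0), np.sin(4 * np.pi * t / 60), np.cos(2 * np.pi * t / 60)],
        axis=-1,
    )
    trajs = [
        Trajectory(w1, dt=0.1, is_periodic=True, period_steps=40),
        Trajectory(w2, dt=0.1, is_periodic=True, period_steps=60),
    ]
    return AttractorLibrary.from_trajectories(trajs, scheme=coding)


class TestFit:
    def test_same_seed_same_readout(self):
        lib = _two_wave_library()
        a = ReservoirMemory(N=200, seed=4, train_steps=2500).fit(lib)
        b = ReservoirMemory(N=200, seed=4, train_steps=2500).fit(lib)
        assert np.array_equal(a.weights_.W_out, b.weights_.W_out)

    def test_library_order_invariance_without_noise(self):
        # permuting the stored states only permutes the codes; the pooled
        # regression is the same sum, so the readout matches numerically
        lib = _two_wave_library()
        swapped = AttractorLibrary(
            trajectories=lib.trajectories[::-1],
            coding=type(lib.coding)(scheme="scalar", K=2, codes=lib.coding.codes[::-1]),
            names=lib.names[::-1],
        )
        kw = dict(N=150, seed=4, train_steps=2000, train_noise=0.0)
        a = ReservoirMemory(**kw).fit(lib)
        b = ReservoirMemory(**kw).fit(swapped)
        # identical regression up to float summation order in the pooled sums
        assert np.allclose(a.weights_.W_out, b.weights_.W_out, rtol=1e-3, atol=1e-5)

    def test_distinct_codes_give_distinct_bias_vectors(self, six_mem):
        rc = six_mem.weights_
        codes = six_mem.library_.coding.codes
        biases = codes @ rc.W_index.T
        for i in range(len(codes)):
            for j in range(i + 1, len(codes)):
                assert np.linalg.norm(biases[i] - biases[j]) > 1e-6

    def test_too_short_trajectory_rejected(self):
        t = Trajectory(np.random.default_rng(0).standard_normal((50, 3)))
        with pytest.raises(ValueError, match="too short"):
            ReservoirMemory(N=100, washout=200).fit([t])


class TestRecall:
    def test_recall_periodic_state_matches_period(self):
        lib = _two_wave_library()
        mem = ReservoirMemory(N=300, seed=2, train_steps=2500).fit(lib)
        for i, target in ((1, 40), (2, 60)):
            res = mem.recall(i, n_steps=600, seed=3, settle_steps=800)
            assert not res.diverged
            assert average_period(res.trajectory, 0) == pytest.approx(target, rel=0.02)

    def test_invalid_state_index(self, six_mem):
        with pytest.raises(ValueError, match="out of range"):
            six_mem.recall(0)
        with pytest.raises(ValueError, match="out of range"):
            six_mem.recall(7)

    def test_unfitted_estimator_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            ReservoirMemory().recall(1)

    def test_sklearn_param_round_trip(self):
        mem = ReservoirMemory(N=123, leak=0.4)
        params = mem.get_params()
        assert params["N"] == 123
        clone = ReservoirMemory(**params)
        assert clone.leak == 0.4


class TestSwitching:
    def test_switch_to_same_state_keeps_label(self, six_mem, six_clf):
        from rcmem.control import source_snapshots, switch_and_classify

        snaps = source_snapshots(six_mem, 2, 3, seed=1)
        for snap in snaps:
            ok, label, _ = switch_and_classify(six_mem, six_clf, snap, 2)
            assert ok and label == 2

    def test_switch_inherits_running_state(self, six_mem):
        snap_r = np.full(1000, 0.1)
        snap_v = np.zeros(3)
        a = six_mem.switch_index(4, snap_r, snap_v, n_steps=50)
        b = six_mem.switch_index(4, snap_r, snap_v, n_steps=50)
        assert np.array_equal(a.trajectory.values, b.trajectory.values)


class TestIndexFreeAndSeparate:
    def test_indexfree_has_no_index_channel(self, indexfree_mem):
        assert indexfree_mem.weights_.params.C_index == 0
        assert indexfree_mem.library_.coding is None

    def test_separate_readout_equals_single_state_training(self):
        lib = _two_wave_library(coding=None)
        kw = dict(N=150, seed=9, train_steps=2000)
        mem, per_state = train_separate_readouts(lib, **kw)
        solo_lib = AttractorLibrary(trajectories=lib.trajectories[:1], coding=None)
        solo = ReservoirMemory(**kw).fit(solo_lib)
        # same reservoir seed, same first-segment noise draws -> identical
        # regression problem -> identical readout
        assert np.allclose(per_state[0], solo.weights_.W_out, atol=1e-9)

    def test_separate_readouts_reconstruct_their_states(self):
        lib = _two_wave_library(coding=None)
        mem, per_state = train_separate_readouts(lib, N=300, seed=2, train_steps=2500)
        import copy

        from rcmem.reservoir import closed_loop, drive

        for i, target in ((1, 40), (2, 60)):
            rc = copy.copy(mem.weights_)
            rc.W_out = per_state[i - 1]
            u = lib.trajectories[i - 1].values
            states = drive(rc, u[:300])
            res = closed_loop(rc, r0=states[-1], v0=u[300], n_steps=600)
            assert average_period(res.trajectory, 0) == pytest.approx(target, rel=0.02)
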