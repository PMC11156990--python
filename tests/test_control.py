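"""Transition matrices, detour planning, feedback and cue control."""

import itertools

import numpy as np
import pytest

from rcmem.control import (
    ControlConfig,
    TransitionMatrix,
    cue_control_switch,
    dest_source_variance,
    estimate_transition_matrix,
    execute_detour,
    feedback_control_switch,
    plan_detour,
    source_snapshots,
    sweep_control_settings,
    switch_and_classify,
)


def _bruteforce_best_path(eta, i, j, max_len):
    """Independent oracle: enumerate all simple paths with <= max_len hops."""
    K = eta.shape[0]
    best_rate, best_path = eta[i - 1, j - 1], [i, j]
    nodes = [n for n in range(1, K + 1) if n not in (i, j)]
    for n_mid in range(1, max_len):
        for mids in itertools.permutations(nodes, n_mid):
            path = [i, *mids, j]
            rate = np.prod([eta[a - 1, b - 1] for a, b in zip(path, path[1:])])
            if rate > best_rate:
                best_rate, best_path = rate, path
    return best_path, best_rate


class TestPlanDetour:
    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            eta = rng.uniform(0, 1, size=(6, 6))
            np.fill_diagonal(eta, 1.0)
            T = TransitionMatrix(eta=eta, n_trials=1)
            i, j = rng.integers(1, 7, size=2)
            while j == i:
                j = rng.integers(1, 7)
            for max_len in (1, 2, 3):
                path, rate = plan_detour(T, int(i), int(j), max_len=max_len)
                opath, orate = _bruteforce_best_path(eta, int(i), int(j), max_len)
                assert rate == pytest.approx(orate, abs=1e-12)
                assert path == opath

    def test_direct_path_when_already_best(self):
        eta = np.full((3, 3), 0.1)
        np.fill_diagonal(eta, 1.0)
        eta[0, 2] = 0.9
        path, rate = plan_detour(TransitionMatrix(eta, 1), 1, 3)
        assert path == [1, 3] and rate == pytest.approx(0.9)

    def test_prefers_profitable_intermediate_hop(self):
        # eta_24 * eta_46 > eta_26 -> detour through 4
        eta = np.full((6, 6), 0.0)
        np.fill_diagonal(eta, 1.0)
        eta[1, 5] = 0.5
        eta[1, 3] = 0.95
        eta[3, 5] = 0.9
        path, rate = plan_detour(TransitionMatrix(eta, 1), 2, 6, max_len=2)
        assert path == [2, 4, 6]
        assert rate == pytest.approx(0.95 * 0.9)

    def test_all_zero_row_returns_direct(self):
        eta = np.zeros((4, 4))
        np.fill_diagonal(eta, 1.0)
        path, rate = plan_detour(TransitionMatrix(eta, 1), 2, 3, max_len=3)
        assert path == [2, 3] and rate == 0.0


class TestTransitionMatrix:
    def test_entries_valid_and_diagonal_high(self, six_mem, six_clf):
        T = estimate_transition_matrix(six_mem, six_clf, n_trials_per_pair=3, seed=7)
        assert np.all((T.eta >= 0) & (T.eta <= 1))
        assert np.all(np.diag(T.eta) >= 0.5)

    def test_variance_helper_ignores_diagonal(self):
        eta = np.eye(3)
        eta[0, 1] = eta[1, 0] = 0.5
        eta[0, 2] = eta[1, 2] = eta[2, 0] = eta[2, 1] = 0.5
        dv, sv = dest_source_variance(TransitionMatrix(eta, 1))
        assert dv == pytest.approx(0.0)
        assert sv == pytest.approx(0.0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            TransitionMatrix(np.array([[1.0, 1.5], [0.0, 1.0]]), 1)


class TestControlStrategies:
    def test_path_of_one_hop_equals_plain_switch(self, six_mem, six_clf):
        snap = source_snapshots(six_mem, 1, 1, seed=3)[0]
        ok_a, label_a, res = switch_and_classify(six_mem, six_clf, snap, 4)
        ok_b, labels = execute_detour(six_mem, six_clf, [1, 4], snap)
        assert ok_a == ok_b and labels[-1] == label_a

    def test_feedback_control_zero_cycles_when_already_correct(self, six_mem, six_clf):
        snap = source_snapshots(six_mem, 2, 1, seed=4)[0]
        out = feedback_control_switch(six_mem, six_clf, 2, snap, ControlConfig(max_cycles=2))
        assert out.success and out.cycles_used == 0

    def test_cue_len_zero_is_plain_switch(self, six_mem, six_clf):
        snap = source_snapshots(six_mem, 1, 1, seed=5)[0]
        ok_plain, _, _ = switch_and_classify(six_mem, six_clf, snap, 3)
        ok_cue = cue_control_switch(six_mem, six_clf, 3, snap, cue_len=0)
        assert ok_plain == ok_cue

    def test_cue_longer_than_reference_rejected(self, six_mem, six_clf):
        snap = source_snapshots(six_mem, 1, 1, seed=6)[0]
        with pytest.raises(ValueError, match="cue longer"):
            cue_control_switch(six_mem, six_clf, 3, snap, cue_len=10**6)

    def test_sweep_has_twelve_rows_and_empty_pool_ok(self, six_mem, six_clf):
        rows = sweep_control_settings(six_mem, six_clf, [], max_cycles=1)
        assert len(rows) == 12
        assert {(r["T_n"], r["sigma"]) for r in rows} == {
            (tn, sg) for tn in (1, 3, 10, 30) for sg in (0.3, 1.0, 3.0)
        }

    def test_reach_time_formula(self):
        cfg = ControlConfig(T_n=10, T_c=100, sigma=1.0)
        assert cfg.reach_time(0.5) == pytest.approx(220.0)
        assert cfg.reach_time(0.0) == np.inf

    def test_reach_time_matches_geometric_trials(self):
        # independent oracle: simulate geometric retries with success
        # probability eta; mean time ~ (T_n + T_c) / eta
        rng = np.random.default_rng(0)
        eta, T_n, T_c = 0.3, 10, 100
        sims = []
        for _ in range(4000):
            cycles = 1
            while rng.uniform() > eta:
                cycles += 1
            sims.append(cycles * (T_n + T_c))
        cfg = ControlConfig(T_n=T_n, T_c=T_c, sigma=1.0)
        assert np.mean(sims) == pytest.approx(cfg.reach_time(eta), rel=0.2)
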