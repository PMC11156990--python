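"""Switching between stored attractors and the control strategies that make
switching reliable.

Changing the index value mid-run swaps the closed-loop dynamical equations
while the hidden state and last output are inherited; the switch succeeds
only if that inherited state lies in the destination attractor's basin.
This module estimates the resulting K-by-K success-rate (transition) matrix
and implements the three non-invasive strategies that raise the success
rate: tactical detours through intermediate states, classifier-feedback
random perturbations, and cue-based warm-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import NONE_LABEL, ReservoirClassifier
from .memory import ReservoirMemory
from .reservoir import closed_loop, drive

__all__ = [
    "TransitionMatrix",
    "ControlConfig",
    "SwitchSnapshot",
    "source_snapshots",
    "switch_and_classify",
    "estimate_transition_matrix",
    "dest_source_variance",
    "harvest_failures",
    "plan_detour",
    "execute_detour",
    "feedback_control_switch",
    "cue_control_switch",
    "sweep_control_settings",
]

#: steps of closed-loop settling between an index switch and classification
SETTLE_STEPS = 100
#: post-settle steps handed to the classifier (>= washout + window)
CLASSIFY_STEPS = 200


@dataclass
class TransitionMatrix:
    """eta[i-1, j-1] = empirical success probability of the direct switch
    from stored state i to stored state j."""

    eta: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        if self.eta.ndim != 2 or self.eta.shape[0] != self.eta.shape[1]:
            raise ValueError("eta must be square")
        if np.any((self.eta < 0) | (self.eta > 1)):
            raise ValueError("success rates must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.eta.shape[0]


@dataclass
class ControlConfig:
    """Settings of the perturb-and-classify feedback controller.

    ``T_n``: steps of Gaussian noise per perturbation; ``T_c``: steps used
    for the classifier's decision; ``sigma``: noise standard deviation;
    ``max_cycles``: give-up bound."""

    T_n: int = 10
    T_c: int = CLASSIFY_STEPS
    sigma: float = 1.0
    max_cycles: int = 10

    def __post_init__(self) -> None:
        if min(self.T_n, self.T_c, self.max_cycles) <= 0 or self.sigma <= 0:
            raise ValueError("all control settings must be positive")

    def reach_time(self, eta_ij: float) -> float:
        """Expected time to reach the destination: (T_n + T_c) / eta_ij."""
        if eta_ij <= 0:
            return np.inf
        return (self.T_n + self.T_c) / eta_ij


@dataclass
class SwitchSnapshot:
    """A running-state snapshot (hidden state + last output) taken while the
    memory operates on ``source``; the starting point of one switch trial."""

    source: int
    r: np.ndarray
    v: np.ndarray
    target: int | None = None  # filled when harvested as a failure case


def source_snapshots(
    mem: ReservoirMemory,
    i: int,
    n_snapshots: int,
    seed: int = 0,
    run_steps: int = 1000,
    warm_steps: int = 300,
) -> list[SwitchSnapshot]:
    """Snapshots of the closed loop running on stored state ``i`` at random
    time steps: warm up on the reference series, run closed loop, and sample
    (r, v) pairs uniformly over the run."""
    rng = np.random.default_rng(seed)
    lib = mem.library_
    u = lib.trajectories[i - 1].values
    start = int(rng.integers(0, len(u) - warm_steps - 1))
    p = mem._code(i)
    r0 = mem.random_hidden_state(int(rng.integers(2**31 - 1)))
    states = drive(mem.weights_, u[start : start + warm_steps], p=p, r0=r0)
    res = closed_loop(
        mem.weights_,
        p=p,
        r0=states[-1],
        v0=u[start + warm_steps],
        n_steps=run_steps,
        return_states=True,
    )
    times = rng.integers(0, run_steps, size=n_snapshots)
    return [
        SwitchSnapshot(source=i, r=res.states[t].copy(), v=res.trajectory.values[t].copy())
        for t in times
    ]


def switch_and_classify(
    mem: ReservoirMemory,
    clf: ReservoirClassifier,
    snap: SwitchSnapshot,
    j: int,
    settle_steps: int = SETTLE_STEPS,
) -> tuple[bool, int, "GenerationResult"]:
    """One direct switch: continue under p_j from the snapshot, settle,
    classify. Returns (success, label, generation result)."""
    res = mem.switch_index(j, snap.r, snap.v, n_steps=settle_steps + CLASSIFY_STEPS)
    label, _ = clf.classify(res.trajectory.values[settle_steps:])
    return label == j, label, res


def estimate_transition_matrix(
    mem: ReservoirMemory,
    clf: ReservoirClassifier,
    n_trials_per_pair: int = 10,
    seed: int = 0,
    include_diagonal: bool = True,
) -> TransitionMatrix:
    """Empirical switch success rates over all ordered state pairs, with
    switches made at random times of the source run."""
    K = mem.n_states_
    eta = np.ones((K, K))
    rng = np.random.default_rng(seed)
    for i in range(1, K + 1):
        snaps = source_snapshots(
            mem, i, n_snapshots=n_trials_per_pair * K, seed=int(rng.integers(2**31 - 1))
        )
        it = iter(snaps)
        for j in range(1, K + 1):
            if i == j and not include_diagonal:
                continue
            wins = 0
            for _ in range(n_trials_per_pair):
                ok, _, _ = switch_and_classify(mem, clf, next(it), j)
                wins += ok
            eta[i - 1, j - 1] = wins / n_trials_per_pair
    return TransitionMatrix(eta=eta, n_trials=n_trials_per_pair)


def dest_source_variance(T: TransitionMatrix) -> tuple[float, float]:
    """(variance across destination columns, variance across source rows)
    of the off-diagonal success rates — the destination variance dominating
    means success depends mostly on where you switch *to*."""
    eta = T.eta.copy().astype(float)
    K = T.K
    mask = ~np.eye(K, dtype=bool)
    col_means = np.array([eta[:, j][mask[:, j]].mean() for j in range(K)])
    row_means = np.array([eta[i, :][mask[i, :]].mean() for i in range(K)])
    return float(np.var(col_means)), float(np.var(row_means))


def harvest_failures(
    mem: ReservoirMemory,
    clf: ReservoirClassifier,
    n_switches: int,
    seed: int = 0,
) -> tuple[list[SwitchSnapshot], int]:
    """Run random direct switches and keep the failing start states as a
    test pool for the control strategies. Returns (failures, n_attempted)."""
    rng = np.random.default_rng(seed)
    K = mem.n_states_
    failures: list[SwitchSnapshot] = []
    per_source = max(1, n_switches // K)
    attempted = 0
    for i in range(1, K + 1):
        snaps = source_snapshots(mem, i, per_source, seed=int(rng.integers(2**31 - 1)))
        for snap in snaps:
            j = int(rng.integers(1, K + 1))
            while j == i:
                j = int(rng.integers(1, K + 1))
            attempted += 1
            ok, _, _ = switch_and_classify(mem, clf, snap, j)
            if not ok:
                snap.target = j
                failures.append(snap)
    return failures, attempted


# ---------------------------------------------------------------------------
# Strategy 1: tactical detour


def plan_detour(
    T: TransitionMatrix, i: int, j: int, max_len: int = 3, exclude_direct: bool = False
) -> tuple[list[int], float]:
    """Best chain of index switches from i to j with at most ``max_len``
    hops, maximizing the product of per-hop success rates.

    Exhaustive search over simple paths (K is small); returns the path
    including both endpoints and its estimated success probability.
    ``exclude_direct`` forces at least one intermediate state — the right
    mode when correcting a switch that is already known to have failed,
    since repeating the identical direct switch is deterministic.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    K = T.K
    eta = T.eta
    best_path = [i, j]
    best_rate = -1.0 if (exclude_direct and max_len > 1 and K > 2) else eta[i - 1, j - 1]

    def extend(path: list[int], rate: float) -> None:
        nonlocal best_path, best_rate
        last = path[-1]
        if last == j and len(path) > 1:
            direct = len(path) == 2
            if rate > best_rate and not (exclude_direct and direct):
                best_rate, best_path = rate, list(path)
            return
        if len(path) - 1 >= max_len:
            return
        for nxt in range(1, K + 1):
            if nxt in path:
                continue
            if nxt != j and len(path) == max_len:
                continue
            extend(path + [nxt], rate * eta[last - 1, nxt - 1])

    extend([i], 1.0)
    if best_rate < 0:  # no detour exists (tiny K); fall back to the direct hop
        return [i, j], float(eta[i - 1, j - 1])
    return best_path, float(best_rate)


def execute_detour(
    mem: ReservoirMemory,
    clf: ReservoirClassifier,
    path: list[int],
    snap: SwitchSnapshot,
) -> tuple[bool, list[int]]:
    """Perform the chain of switches of a planned detour from a running
    state; each hop settles and is classified. Returns (reached final
    target, per-hop labels)."""
    if len(path) < 2:
        raise ValueError("a detour path needs at least two states")
    r, v = snap.r, snap.v
    labels: list[int] = []
    for hop in path[1:]:
        res = mem.switch_index(hop, r, v, n_steps=SETTLE_STEPS + CLASSIFY_STEPS)
        label, _ = clf.classify(res.trajectory.values[SETTLE_STEPS:])
        labels.append(label)
        r = res.r_final
        v = res.trajectory.values[-1]
    return labels[-1] == path[-1], labels


# ---------------------------------------------------------------------------
# Strategy 2: classifier feedback with random perturbations


def _perturbed_steps(mem: ReservoirMemory, p, r, v, T_n: int, sigma: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Run T_n steps with Gaussian noise *replacing* the input.

    The random signal takes over the input port entirely during the
    perturbation: a failed switch often parks the loop on a strongly
    attracting untrained state whose output is far out of range, where
    merely adding noise to the fed-back output would be negligible."""
    rc = mem.weights_
    leak = rc.params.leak
    const = rc.bias + (rc.W_index @ np.atleast_1d(p) if rc.params.C_index else 0.0)
    mode = rc.params.readout_features
    for _ in range(T_n):
        u = sigma * rng.standard_normal(rc.params.D_in)
        r = (1.0 - leak) * r + leak * np.tanh(rc.A @ r + u @ rc.W_in.T + const)
        feat = np.concatenate([r, r * r]) if mode == "linear_plus_square" else r
        v = np.clip(rc.W_out @ feat, -rc.guard_bound, rc.guard_bound)
    return r, v


@dataclass
class ControlOutcome:
    success: bool
    cycles_used: int
    label: int = NONE_LABEL


def feedback_control_switch(
    mem: ReservoirMemory,
    clf: ReservoirClassifier,
    j: int,
    snap: SwitchSnapshot,
    cfg: ControlConfig = ControlConfig(),
    seed: int = 0,
) -> ControlOutcome:
    """Perturb-and-classify loop: classify the output under p_j; if it is not
    the target, inject ``T_n`` steps of Gaussian input noise and try again,
    up to ``max_cycles`` cycles."""
    rng = np.random.default_rng(seed)
    p = mem._code(j)
    res = mem.switch_index(j, snap.r, snap.v, n_steps=SETTLE_STEPS + cfg.T_c)
    label, _ = clf.classify(res.trajectory.values[-cfg.T_c :])
    if label == j:
        return ControlOutcome(success=True, cycles_used=0, label=label)
    r, v = res.r_final, res.trajectory.values[-1]
    for cycle in range(1, cfg.max_cycles + 1):
        r, v = _perturbed_steps(mem, p, r, v, cfg.T_n, cfg.sigma, rng)
        res = closed_loop(mem.weights_, p=p, r0=r, v0=v, n_steps=SETTLE_STEPS + cfg.T_c)
        label, _ = clf.classify(res.trajectory.values[-cfg.T_c :])
        r, v = res.r_final, res.trajectory.values[-1]
        if label == j:
            return ControlOutcome(success=True, cycles_used=cycle, label=label)
    return ControlOutcome(success=False, cycles_used=cfg.max_cycles, label=label)


# ---------------------------------------------------------------------------
# Strategy 3: cue-based warm-up


def cue_control_switch(
    mem: ReservoirMemory,
    clf: ReservoirClassifier,
    j: int,
    snap: SwitchSnapshot,
    cue_len: int,
    seed: int = 0,
) -> bool:
    """Switch to p_j and warm the reservoir with ``cue_len`` steps of the
    target attractor's own time series before letting it run free."""
    rng = np.random.default_rng(seed)
    u = mem.library_.trajectories[j - 1].values
    p = mem._code(j)
    r, v = snap.r, snap.v
    if cue_len > len(u) - 1:
        raise ValueError("cue longer than the available reference series")
    if cue_len > 0:
        start = int(rng.integers(0, len(u) - cue_len - 1))
        states = drive(mem.weights_, u[start : start + cue_len], p=p, r0=r)
        r, v = states[-1], u[start + cue_len]
    res = closed_loop(mem.weights_, p=p, r0=r, v0=v, n_steps=SETTLE_STEPS + CLASSIFY_STEPS)
    label, _ = clf.classify(res.trajectory.values[SETTLE_STEPS:])
    return label == j


# ---------------------------------------------------------------------------
# Parameter sweep


def sweep_control_settings(
    mem: ReservoirMemory,
    clf: ReservoirClassifier,
    failure_pool: list[SwitchSnapshot],
    T_n_values: tuple[int, ...] = (1, 3, 10, 30),
    sigma_values: tuple[float, ...] = (0.3, 1.0, 3.0),
    max_cycles: int = 10,
    seed: int = 0,
) -> list[dict]:
    """Evaluate the feedback controller over the grid of perturbation lengths
    and noise levels on a harvested failure pool; one row per setting with
    correction rates after one cycle and after ``max_cycles``."""
    rows: list[dict] = []
    rng = np.random.default_rng(seed)
    for T_n in T_n_values:
        for sigma in sigma_values:
            cfg = ControlConfig(T_n=T_n, sigma=sigma, max_cycles=max_cycles)
            one = 0
            final = 0
            for snap in failure_pool:
                outcome = feedback_control_switch(
                    mem, clf, snap.target, snap, cfg, seed=int(rng.integers(2**31 - 1))
                )
                one += outcome.success and outcome.cycles_used <= 1
                final += outcome.success
            n = max(1, len(failure_pool))
            rows.append(
                {
                    "T_n": T_n,
                    "sigma": sigma,
                    "corrected_1_cycle": one / n,
                    f"corrected_{max_cycles}_cycles": final / n,
                }
            )
    return rows
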