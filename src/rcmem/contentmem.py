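"""Content-addressable (index-free) recall.

An index-free memory is trained exactly like the indexed one but with no
index channel: the K stored attractors coexist as multistable states of one
autonomous reservoir. Retrieval drives the network with a short cue time
series from the target attractor — full, partial (missing dimensions
compensated by feeding the model's own output back into those input
channels), or noisy — and then releases it into closed-loop operation.
This module measures recall success versus cue length, the basin structure
in hidden space, robustness to hidden-state kicks, the approach of the
hidden state to the target's embedding during warming, and noise-induced
itinerancy among the stored states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import NONE_LABEL, ReservoirClassifier
from .memory import ReservoirMemory
from .reservoir import closed_loop, drive

__all__ = [
    "CueSpec",
    "RecallResult",
    "BasinSlice",
    "recall_with_cue",
    "recall_partial_cue",
    "recall_noisy_cue",
    "success_vs_cue_length",
    "basin_slice",
    "perturbation_robustness",
    "embedding_cloud",
    "distance_to_embedding",
    "neuron_noise_itinerancy",
]

#: closed-loop steps generated after the cue before classification
GENERATE_STEPS = 250


@dataclass
class CueSpec:
    """Recipe for one cue-recall trial.

    ``dims_present`` selects the cue components actually supplied (1-based;
    None = all); missing components are compensated by output feedback.
    ``noise_sigma`` adds i.i.d. Gaussian noise to the supplied components.
    """

    state_id: int
    cue_len: int = 50
    dims_present: tuple[int, ...] | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cue_len < 0 or self.noise_sigma < 0:
            raise ValueError("cue_len and noise_sigma must be nonnegative")
        if self.dims_present is not None and len(self.dims_present) == 0 and self.cue_len > 0:
            raise ValueError("dims_present must be nonempty when a cue is supplied")


@dataclass
class RecallResult:
    label: int
    success: bool
    diverged: bool = False


def _cue_segment(mem: ReservoirMemory, cue: CueSpec, rng) -> np.ndarray:
    u = mem.library_.trajectories[cue.state_id - 1].values
    if cue.cue_len > len(u) - 1:
        raise ValueError("cue longer than the available reference series")
    start = int(rng.integers(0, len(u) - cue.cue_len - 1)) if cue.cue_len else 0
    seg = u[start : start + cue.cue_len].copy()
    if cue.noise_sigma > 0 and len(seg):
        seg += cue.noise_sigma * rng.standard_normal(seg.shape)
    return seg


def _hybrid_warmup(
    mem: ReservoirMemory, seg: np.ndarray, dims_present: tuple[int, ...], r: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Warm up with a partial cue: the supplied dimensions come from the cue,
    the missing input channels are rewired to the model's own output."""
    rc = mem.weights_
    leak = rc.params.leak
    const = rc.bias
    mode = rc.params.readout_features
    mask = np.zeros(rc.params.D_in, dtype=bool)
    mask[[d - 1 for d in dims_present]] = True
    v = np.zeros(rc.params.D_in)
    for t in range(len(seg)):
        u = np.where(mask, seg[t], v)
        r = (1.0 - leak) * r + leak * np.tanh(rc.A @ r + u @ rc.W_in.T + const)
        feat = np.concatenate([r, r * r]) if mode == "linear_plus_square" else r
        v = np.clip(rc.W_out @ feat, -rc.guard_bound, rc.guard_bound)
    v_last = np.where(mask, seg[-1], v) if len(seg) else v
    return r, v_last


def recall_with_cue(
    mem: ReservoirMemory,
    clf: ReservoirClassifier,
    cue: CueSpec,
    r0: np.ndarray | None = None,
) -> RecallResult:
    """One cue-recall trial: random initial hidden state, warm-up over the
    cue, closed-loop generation, classification. Success = the classifier
    labels the output as the cued state."""
    if mem.library_.coding is not None:
        raise ValueError("recall_with_cue expects an index-free memory")
    rng = np.random.default_rng(cue.seed)
    if r0 is None:
        r0 = mem.random_hidden_state(int(rng.integers(2**31 - 1)))
    seg = _cue_segment(mem, cue, rng)
    full = cue.dims_present is None or len(cue.dims_present) == mem.n_dims_
    if len(seg) == 0:
        r, v0 = r0, None
    elif full:
        states = drive(mem.weights_, seg, r0=r0)
        r, v0 = states[-1], seg[-1]
    else:
        r, v0 = _hybrid_warmup(mem, seg, cue.dims_present, r0.copy())
    res = closed_loop(mem.weights_, r0=r, v0=v0, n_steps=GENERATE_STEPS)
    label, _ = clf.classify(res.trajectory.values[-(clf.washout + clf.window_steps) :])
    return RecallResult(label=label, success=label == cue.state_id, diverged=res.diverged)


def recall_partial_cue(
    mem: ReservoirMemory, clf: ReservoirClassifier, cue: CueSpec
) -> RecallResult:
    """Cue recall with one or more missing dimensions (feedback-rewired)."""
    if cue.dims_present is None:
        raise ValueError("recall_partial_cue needs an explicit dims_present")
    return recall_with_cue(mem, clf, cue)


def recall_noisy_cue(
    mem: ReservoirMemory, clf: ReservoirClassifier, cue: CueSpec
) -> RecallResult:
    """Cue recall with Gaussian noise on the cue signal."""
    if cue.noise_sigma <= 0:
        raise ValueError("recall_noisy_cue needs noise_sigma > 0")
    return recall_with_cue(mem, clf, cue)


def success_vs_cue_length(
    mem: ReservoirMemory,
    clf: ReservoirClassifier,
    state_id: int,
    cue_lengths: tuple[int, ...] = (0, 5, 10, 20, 50, 100),
    n_trials: int = 30,
    seed: int = 0,
    dims_present: tuple[int, ...] | None = None,
    noise_sigma: float = 0.0,
) -> dict[int, float]:
    """Recall success rate for one stored state at each cue length."""
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for L in cue_lengths:
        wins = 0
        for _ in range(n_trials):
            cue = CueSpec(
                state_id=state_id,
                cue_len=L,
                dims_present=dims_present,
                noise_sigma=noise_sigma,
                seed=int(rng.integers(2**31 - 1)),
            )
            wins += recall_with_cue(mem, clf, cue).success
        out[L] = wins / n_trials
    return out


# ---------------------------------------------------------------------------
# Basins and robustness in hidden space


@dataclass
class BasinSlice:
    """Labels on a 2-D slice of hidden space spanned by two random orthogonal
    perturbation directions around an on-attractor center state."""

    center: np.ndarray
    dir1: np.ndarray
    dir2: np.ndarray
    eps1_grid: np.ndarray
    eps2_grid: np.ndarray
    labels: np.ndarray  # (len(eps1), len(eps2))


def _random_orthonormal_pair(n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    d1 = rng.standard_normal(n)
    d1 /= np.linalg.norm(d1)
    d2 = rng.standard_normal(n)
    d2 -= d1 * (d1 @ d2)
    d2 /= np.linalg.norm(d2)
    return d1, d2


def _label_from_hidden(
    mem: ReservoirMemory, clf: ReservoirClassifier, r0: np.ndarray, v0: np.ndarray | None = None
) -> int:
    res = closed_loop(mem.weights_, r0=r0, v0=v0, n_steps=GENERATE_STEPS)
    label, _ = clf.classify(res.trajectory.values[-(clf.washout + clf.window_steps) :])
    return label


def on_attractor_state(
    mem: ReservoirMemory, state_id: int, seed: int = 0, warm_steps: int = 400
) -> tuple[np.ndarray, np.ndarray]:
    """A hidden state (and matching output) on the embedding of one stored
    attractor, reached by driving with the reference series."""
    rng = np.random.default_rng(seed)
    u = mem.library_.trajectories[state_id - 1].values
    start = int(rng.integers(0, len(u) - warm_steps - 1))
    r0 = mem.random_hidden_state(int(rng.integers(2**31 - 1)))
    states = drive(mem.weights_, u[start : start + warm_steps], p=mem._code(state_id), r0=r0)
    return states[-1], u[start + warm_steps]


def basin_slice(
    mem: ReservoirMemory,
    clf: ReservoirClassifier,
    center: np.ndarray,
    eps_max: float = 3.0,
    grid_n: int = 21,
    seed: int = 0,
    center_v: np.ndarray | None = None,
) -> BasinSlice:
    """Classify the attractor reached from every point of a 2-D grid of
    perturbations of ``center`` along two random orthonormal directions."""
    rng = np.random.default_rng(seed)
    d1, d2 = _random_orthonormal_pair(len(center), rng)
    eps = np.linspace(-eps_max, eps_max, grid_n)
    labels = np.empty((grid_n, grid_n), dtype=int)
    for a, e1 in enumerate(eps):
        for b, e2 in enumerate(eps):
            labels[a, b] = _label_from_hidden(mem, clf, center + e1 * d1 + e2 * d2, v0=center_v)
    return BasinSlice(center=center, dir1=d1, dir2=d2, eps1_grid=eps, eps2_grid=eps, labels=labels)


def perturbation_robustness(
    mem: ReservoirMemory,
    clf: ReservoirClassifier,
    state_id: int,
    magnitudes: tuple[float, ...],
    n_trials: int = 30,
    seed: int = 0,
) -> dict[float, float]:
    """Probability of staying on the desired attractor after a random
    hidden-state kick of each magnitude."""
    rng = np.random.default_rng(seed)
    out: dict[float, float] = {}
    n = mem.weights_.params.N
    for mag in magnitudes:
        wins = 0
        for _ in range(n_trials):
            r, v = on_attractor_state(mem, state_id, seed=int(rng.integers(2**31 - 1)))
            kick = rng.standard_normal(n)
            kick *= mag / np.linalg.norm(kick)
            wins += _label_from_hidden(mem, clf, r + kick, v0=v) == state_id
        out[mag] = wins / n_trials
    return out


# ---------------------------------------------------------------------------
# Distance to the target embedding during warming


def embedding_cloud(
    mem: ReservoirMemory, state_id: int, n_states: int = 1000, seed: int = 0
) -> np.ndarray:
    """Reference cloud of hidden states collected while driving the reservoir
    on the target attractor — a sample of the attractor's embedding."""
    u = mem.library_.trajectories[state_id - 1].values
    washout = 200
    need = washout + n_states
    states = drive(mem.weights_, u[: min(need, len(u))], p=mem._code(state_id))
    return states[washout:]


def distance_to_embedding(
    mem: ReservoirMemory,
    state_id: int,
    max_cue_len: int = 100,
    n_trials: int = 50,
    cloud: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance from the hidden state to the target embedding at each step of
    cue warming, over an ensemble of random initial states.

    Returns (per-trial distances of shape (n_trials, max_cue_len + 1),
    ensemble mean); distances are nearest-neighbor Euclidean against the
    embedding cloud, index 0 being the un-warmed random state.
    """
    rng = np.random.default_rng(seed)
    if cloud is None:
        cloud = embedding_cloud(mem, state_id, seed=seed)
    u = mem.library_.trajectories[state_id - 1].values
    dists = np.empty((n_trials, max_cue_len + 1))
    for k in range(n_trials):
        start = int(rng.integers(0, len(u) - max_cue_len - 1))
        r0 = mem.random_hidden_state(int(rng.integers(2**31 - 1)))
        states = drive(mem.weights_, u[start : start + max_cue_len], r0=r0)
        path = np.vstack([r0, states])
        # nearest neighbor in the cloud, batched
        d2 = (
            np.sum(path**2, axis=1)[:, None]
            - 2.0 * path @ cloud.T
            + np.sum(cloud**2, axis=1)[None, :]
        )
        dists[k] = np.sqrt(np.maximum(d2.min(axis=1), 0.0))
    return dists, dists.mean(axis=0)


# ---------------------------------------------------------------------------
# Noise-induced itinerancy


def neuron_noise_itinerancy(
    mem: ReservoirMemory,
    clf: ReservoirClassifier,
    noise_sigma: float,
    n_steps: int = 5000,
    seed: int = 0,
    window: int = 250,
    start_state: int = 1,
) -> tuple[list[int], dict[int, float]]:
    """Closed-loop run with i.i.d. Gaussian noise on every hidden unit at
    every step; consecutive output windows are classified, giving a label
    sequence and occupancy fractions over {states, none}."""
    rng = np.random.default_rng(seed)
    rc = mem.weights_
    leak = rc.params.leak
    const = rc.bias
    mode = rc.params.readout_features
    r, v = on_attractor_state(mem, start_state, seed=seed)
    out = np.empty((n_steps, rc.params.D_in))
    for t in range(n_steps):
        r = (1.0 - leak) * r + leak * np.tanh(rc.A @ r + v @ rc.W_in.T + const)
        if noise_sigma > 0:
            r = r + noise_sigma * rng.standard_normal(rc.params.N)
        feat = np.concatenate([r, r * r]) if mode == "linear_plus_square" else r
        v = np.clip(rc.W_out @ feat, -rc.guard_bound, rc.guard_bound)
        out[t] = v
    labels = []
    for start in range(0, n_steps - window + 1, window):
        label, _ = clf.classify(out[start : start + window])
        labels.append(label)
    occupancy: dict[int, float] = {}
    for lab in [NONE_LABEL] + list(range(1, mem.n_states_ + 1)):
        occupancy[lab] = labels.count(lab) / len(labels)
    return labels, occupancy
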