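"""Echo-state-network engine.

A reservoir is a fixed random leaky-tanh recurrent network. Training touches
only a linear readout, fitted by ridge regression on the driven hidden
states. An optional *index channel* injects a constant vector through a
random projection — effectively a per-neuron bias — which is how a single
network stores many attractors, one per index value. Closing the loop
(feeding the readout back as input) turns the driven network into an
autonomous dynamical system whose attractor is selected by the index and/or
by the hidden state it starts from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import linalg
from scipy.linalg import blas

from .dynamics import Trajectory

__all__ = [
    "ReservoirParams",
    "ReservoirWeights",
    "init_reservoir",
    "spectral_radius",
    "drive",
    "make_features",
    "RidgeAccumulator",
    "train_readout",
    "closed_loop",
    "warmup",
    "GenerationResult",
]


@dataclass
class ReservoirParams:
    """Hyperparameters of a reservoir network.

    Defaults are the reference configuration used throughout the package
    for three-dimensional targets sampled so that one oscillation cycle
    spans a few dozen steps.
    """

    N: int = 1000
    D_in: int = 3
    C_index: int = 0
    spectral_radius: float = 0.9
    density: float = 0.02
    input_scale: float = 0.3
    index_scale: float = 1.0
    bias_scale: float = 0.2
    leak: float = 0.3
    ridge_beta: float = 1e-6
    readout_features: str = "linear_plus_square"
    washout: int = 200
    guard_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1 or self.D_in < 1 or self.C_index < 0:
            raise ValueError("invalid reservoir dimensions")
        if not 0 < self.leak <= 1 or not 0 < self.density <= 1:
            raise ValueError("leak and density must lie in (0, 1]")
        if self.spectral_radius <= 0 or self.ridge_beta < 0:
            raise ValueError("spectral_radius must be > 0 and ridge_beta >= 0")
        if self.readout_features not in {"linear", "linear_plus_square"}:
            raise ValueError("readout_features must be 'linear' or 'linear_plus_square'")

    @property
    def n_features(self) -> int:
        return self.N if self.readout_features == "linear" else 2 * self.N


@dataclass
class ReservoirWeights:
    """Weight set of one reservoir (readout included once trained)."""

    W_in: np.ndarray  # (N, D_in)
    W_index: np.ndarray  # (N, C_index)
    A: sp.csr_matrix  # (N, N)
    bias: np.ndarray  # (N,)
    params: ReservoirParams
    W_out: np.ndarray | None = None  # (D_in, F)
    guard_bound: float = field(default=np.inf)

    @property
    def trained(self) -> bool:
        return self.W_out is not None


def spectral_radius(A: sp.spmatrix, seed: int = 0) -> float:
    """|lambda_max| of a (sparse) matrix, by Arnoldi iteration with a fixed
    start vector (dense eigensolve for small matrices)."""
    n = A.shape[0]
    if n <= 400:
        return float(np.max(np.abs(np.linalg.eigvals(A.toarray()))))
    v0 = np.ones(n) / np.sqrt(n)
    try:
        vals = spla.eigs(
            A,
            k=3,
            which="LM",
            v0=v0,
            return_eigenvectors=False,
            maxiter=n * 100,
            ncv=min(n - 1, 60),
        )
        return float(np.max(np.abs(vals)))
    except spla.ArpackNoConvergence as exc:
        if exc.eigenvalues is not None and len(exc.eigenvalues):
            return float(np.max(np.abs(exc.eigenvalues)))
        return float(np.max(np.abs(np.linalg.eigvals(A.toarray()))))


def init_reservoir(params: ReservoirParams) -> ReservoirWeights:
    """Construct an untrained reservoir, deterministic given ``params.seed``.

    The recurrent matrix is sparse Erdős–Rényi with uniform[-1, 1] weights,
    rescaled so its spectral radius matches ``params.spectral_radius``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.N
    # keep a minimum average in-degree so small reservoirs are not nilpotent
    density = max(params.density, min(1.0, 10.0 / n))
    for _ in range(5):
        A = sp.random(
            n,
            n,
            density=density,
            format="csr",
            random_state=rng,
            data_rvs=lambda size: rng.uniform(-1.0, 1.0, size),
        )
        rho = spectral_radius(A) if A.nnz else 0.0
        if rho > 1e-12:
            break
    else:
        raise RuntimeError("could not draw a recurrent matrix with nonzero spectral radius")
    A = A * (params.spectral_radius / rho)
    A = sp.csr_matrix(A)
    W_in = rng.uniform(-params.input_scale, params.input_scale, size=(n, params.D_in))
    W_index = rng.uniform(-params.index_scale, params.index_scale, size=(n, params.C_index))
    bias = rng.uniform(-params.bias_scale, params.bias_scale, size=n)
    return ReservoirWeights(W_in=W_in, W_index=W_index, A=A, bias=bias, params=params)


def _index_term(rc: ReservoirWeights, p: np.ndarray | None) -> np.ndarray:
    if rc.params.C_index == 0:
        return np.zeros(rc.params.N)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if p.shape != (rc.params.C_index,):
        raise ValueError(
            f"index vector has shape {p.shape}, expected ({rc.params.C_index},)"
        )
    return rc.W_index @ p


def drive(
    rc: ReservoirWeights,
    u_series: Trajectory | np.ndarray,
    p: np.ndarray | None = None,
    r0: np.ndarray | None = None,
) -> np.ndarray:
    """Open-loop run: iterate the leaky-tanh update over an input series.

    r(t+1) = (1 - leak) r(t) + leak * tanh(A r(t) + W_in u(t) + W_index p + b)

    Returns the hidden states after each input, shape (T, N).
    """
    u = u_series.values if isinstance(u_series, Trajectory) else np.asarray(u_series, float)
    if u.ndim == 1:
        u = u[:, None]
    if u.shape[1] != rc.params.D_in:
        raise ValueError(f"input has {u.shape[1]} dims, reservoir expects {rc.params.D_in}")
    leak = rc.params.leak
    const = rc.bias + _index_term(rc, p)
    r = np.zeros(rc.params.N) if r0 is None else np.asarray(r0, float).copy()
    pre_in = u @ rc.W_in.T  # (T, N), one dense gemm up front
    A = rc.A
    out = np.empty((len(u), rc.params.N))
    for t in range(len(u)):
        r = (1.0 - leak) * r + leak * np.tanh(A @ r + pre_in[t] + const)
        out[t] = r
    return out


def make_features(states: np.ndarray, mode: str) -> np.ndarray:
    """Readout feature map: ``linear`` is the state itself; the default
    ``linear_plus_square`` appends elementwise squares, breaking the odd
    symmetry of tanh."""
    if mode == "linear":
        return states
    return np.concatenate([states, states**2], axis=-1)


class RidgeAccumulator:
    """Streaming normal equations for the ridge readout.

    Accumulates G = sum X X^T and R = sum Y X^T over any number of
    (features, targets) segments, then solves
    W_out = R (G + beta I)^{-1} without materializing the full design.
    """

    def __init__(self, n_features: int, n_targets: int):
        self.G = np.zeros((n_features, n_features))  # upper triangle only
        self.R = np.zeros((n_targets, n_features))
        self.n_samples = 0

    def add(self, feats: np.ndarray, targets: np.ndarray) -> None:
        if len(feats) != len(targets):
            raise ValueError("feature and target sample counts differ")
        if not np.all(np.isfinite(feats)):
            raise FloatingPointError("non-finite features; the driven reservoir diverged")
        # symmetric rank-k update: half the flops of a full gemm
        self.G = blas.dsyrk(1.0, feats, trans=1, beta=1.0, c=self.G, lower=0)
        self.R += targets.T @ feats
        self.n_samples += len(feats)

    def solve(self, beta: float) -> np.ndarray:
        if self.n_samples == 0:
            raise ValueError("no training samples accumulated")
        G = np.triu(self.G, 1)
        G = G + G.T + np.diag(np.diag(self.G))
        G += beta * np.eye(G.shape[0])
        try:
            c, low = linalg.cho_factor(G)
            W = linalg.cho_solve((c, low), self.R.T).T
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular regression system; use ridge_beta > 0"
            ) from exc
        if not np.all(np.isfinite(W)):
            raise np.linalg.LinAlgError("non-finite readout; use ridge_beta > 0")
        return W


def train_readout(
    states: np.ndarray | list[np.ndarray],
    targets: np.ndarray | list[np.ndarray],
    beta: float,
    feature_mode: str = "linear_plus_square",
) -> np.ndarray:
    """Ridge-regression readout from hidden states to targets.

    ``states``/``targets`` may be single arrays or lists of per-segment
    arrays (washout removal is the caller's responsibility).
    """
    if isinstance(states, np.ndarray):
        states, targets = [states], [targets]
    feats0 = make_features(states[0], feature_mode)
    acc = RidgeAccumulator(feats0.shape[1], np.atleast_2d(targets[0]).shape[-1])
    for s, y in zip(states, targets):
        acc.add(make_features(s, feature_mode), np.atleast_2d(y))
    return acc.solve(beta)


@dataclass
class GenerationResult:
    """Output of a closed-loop run: the generated trajectory, the final
    hidden state, and whether the divergence guard tripped (the signal of a
    failed recall). ``states`` holds the full hidden-state history when
    requested."""

    trajectory: Trajectory
    r_final: np.ndarray
    diverged: bool = False
    states: np.ndarray | None = None


def closed_loop(
    rc: ReservoirWeights,
    p: np.ndarray | None = None,
    r0: np.ndarray | None = None,
    n_steps: int = 1000,
    v0: np.ndarray | None = None,
    dt: float = 1.0,
    return_states: bool = False,
) -> GenerationResult:
    """Autonomous generation: the readout output is fed back as input.

    The run stops early (and is flagged) if any output component exceeds the
    divergence guard bound set at training time.
    """
    if not rc.trained:
        raise ValueError("reservoir has no trained readout")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    leak = rc.params.leak
    const = rc.bias + _index_term(rc, p)
    mode = rc.params.readout_features
    A = rc.A
    W_in_T = rc.W_in.T
    W_out = rc.W_out
    r = np.zeros(rc.params.N) if r0 is None else np.asarray(r0, float).copy()
    v = np.zeros(rc.params.D_in) if v0 is None else np.asarray(v0, float).copy()
    out = np.empty((n_steps, rc.params.D_in))
    states = np.empty((n_steps, rc.params.N)) if return_states else None
    diverged = False
    guard = rc.guard_bound
    for t in range(n_steps):
        r = (1.0 - leak) * r + leak * np.tanh(A @ r + v @ W_in_T + const)
        feat = np.concatenate([r, r * r]) if mode == "linear_plus_square" else r
        v = W_out @ feat
        if not np.all(np.isfinite(v)) or np.max(np.abs(v)) > guard:
            # clip and keep running: the hidden state is bounded by tanh, so
            # the loop can still fall back onto a stored attractor; the flag
            # records that the run left the trained output range
            diverged = True
            v = np.clip(np.nan_to_num(v, nan=guard, posinf=guard, neginf=-guard), -guard, guard)
        out[t] = v
        if return_states:
            states[t] = r
    if len(out) < 2:  # keep the Trajectory invariant (T >= 2)
        out = np.vstack([out, out[-1:]])
    traj = Trajectory(out, dt=dt, name="closed_loop")
    return GenerationResult(trajectory=traj, r_final=r, diverged=diverged, states=states)


def warmup(
    rc: ReservoirWeights,
    cue: Trajectory | np.ndarray | None,
    p: np.ndarray | None = None,
    r0: np.ndarray | None = None,
) -> np.ndarray:
    """Open-loop drive over a (possibly empty) cue; returns the final hidden
    state for subsequent closed-loop continuation."""
    r = np.zeros(rc.params.N) if r0 is None else np.asarray(r0, float).copy()
    if cue is None:
        return r
    u = cue.values if isinstance(cue, Trajectory) else np.asarray(cue, float)
    if len(u) == 0:
        return r
    states = drive(rc, u, p=p, r0=r)
    return states[-1]
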