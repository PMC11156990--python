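"""Location-addressable attractor memory.

:class:`ReservoirMemory` is a scikit-learn-style estimator: ``fit`` drives
one reservoir open-loop over every library attractor together with that
attractor's index code and solves a single ridge readout over the pooled
hidden states ("batch learning"). After fitting, any stored attractor is
retrieved by running the network closed-loop with the attractor's index
value; switching the index mid-run toggles the autonomous dynamics between
stored attractors while the hidden state is inherited across the switch.

With ``coding=None`` (no index channel) the same estimator trains an
*index-free*, content-addressable memory whose stored attractors coexist as
multistable states; retrieval by cue lives in :mod:`rcmem.contentmem`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .coding import AttractorLibrary
from .dynamics import Trajectory
from .reservoir import (
    GenerationResult,
    ReservoirParams,
    ReservoirWeights,
    RidgeAccumulator,
    closed_loop,
    drive,
    init_reservoir,
    make_features,
    warmup,
)

__all__ = ["ReservoirMemory", "train_memory", "train_indexfree", "train_separate_readouts"]


class ReservoirMemory(BaseEstimator):
    """A single reservoir network storing K dynamical attractors.

    Parameters mirror :class:`rcmem.reservoir.ReservoirParams`;
    ``train_steps`` is the post-washout number of regression samples taken
    per attractor (equal across attractors so no state dominates the fit).

    Attributes (after ``fit``)
    --------------------------
    weights_ : ReservoirWeights
        All weight matrices including the trained readout.
    library_ : AttractorLibrary
        The fitted library (normalized trajectories and codes).
    n_states_ : int
        Number of stored attractors K.
    """

    def __init__(
        self,
        N: int = 1000,
        spectral_radius: float = 0.9,
        density: float = 0.02,
        input_scale: float = 1.0,
        index_scale: float = 0.3,
        bias_scale: float = 0.2,
        leak: float = 0.5,
        ridge_beta: float = 1e-6,
        readout_features: str = "linear_plus_square",
        washout: int = 200,
        train_steps: int = 5000,
        train_noise: float = 0.03,
        guard_factor: float = 10.0,
        seed: int = 0,
    ):
        self.N = N
        self.spectral_radius = spectral_radius
        self.density = density
        self.input_scale = input_scale
        self.index_scale = index_scale
        self.bias_scale = bias_scale
        self.leak = leak
        self.ridge_beta = ridge_beta
        self.readout_features = readout_features
        self.washout = washout
        self.train_steps = train_steps
        self.train_noise = train_noise
        self.guard_factor = guard_factor
        self.seed = seed

    # -- construction -----------------------------------------------------

    def _make_params(self, library: AttractorLibrary) -> ReservoirParams:
        c_index = library.coding.n_channels if library.coding is not None else 0
        return ReservoirParams(
            N=self.N,
            D_in=library.n_dims,
            C_index=c_index,
            spectral_radius=self.spectral_radius,
            density=self.density,
            input_scale=self.input_scale,
            index_scale=self.index_scale,
            bias_scale=self.bias_scale,
            leak=self.leak,
            ridge_beta=self.ridge_beta,
            readout_features=self.readout_features,
            washout=self.washout,
            guard_factor=self.guard_factor,
            seed=self.seed,
        )

    def _code(self, i: int) -> np.ndarray | None:
        if self.library_.coding is None:
            return None
        return self.library_.coding.code(i)

    def _driven_segments(self, rc: ReservoirWeights, library: AttractorLibrary):
        """Yield (features, next-step targets) per attractor, washout removed.

        A small Gaussian perturbation (``train_noise``) is added to the
        *input* during the drive while the regression targets stay clean:
        the readout then learns to contract a whole tube around the target
        orbit back onto it, which is what makes the stored attractors stable
        under closed-loop feedback and gives them usable basins.
        """
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x5EED]))
        for i, traj in enumerate(library.trajectories, start=1):
            u = traj.values
            need = self.washout + self.train_steps + 1
            if len(u) < self.washout + 2:
                raise ValueError(
                    f"trajectory {i} too short ({len(u)} steps) for washout {self.washout}"
                )
            u = u[: min(len(u), need)]
            p = library.coding.code(i) if library.coding is not None else None
            u_in = u[:-1]
            if self.train_noise > 0:
                u_in = u_in + self.train_noise * rng.standard_normal(u_in.shape)
            states = drive(rc, u_in, p=p)
            feats = make_features(states[self.washout :], self.readout_features)
            targets = u[self.washout + 1 :]
            yield i, p, feats, targets

    def fit(self, X: AttractorLibrary | list, y=None) -> "ReservoirMemory":
        """Store all attractors of a library in one reservoir.

        ``X`` may be an :class:`AttractorLibrary` or a plain list of
        trajectories/arrays (then a scalar coding p_i = i is attached).
        """
        library = (
            X
            if isinstance(X, AttractorLibrary)
            else AttractorLibrary.from_trajectories(
                [t if isinstance(t, Trajectory) else Trajectory(t) for t in X]
            )
        )
        params = self._make_params(library)
        rc = init_reservoir(params)
        self.library_ = library
        acc = RidgeAccumulator(params.n_features, library.n_dims)
        amp = 0.0
        for _i, _p, feats, targets in self._driven_segments(rc, library):
            acc.add(feats, targets)
            amp = max(amp, float(np.max(np.abs(targets))))
        rc.W_out = acc.solve(self.ridge_beta)
        rc.guard_bound = self.guard_factor * amp
        self.weights_ = rc
        self.n_states_ = library.K
        self.n_dims_ = library.n_dims
        return self

    # -- retrieval ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise ValueError("this ReservoirMemory instance is not fitted yet")

    def _check_state(self, i: int) -> None:
        if not 1 <= i <= self.n_states_:
            raise ValueError(f"state index {i} out of range 1..{self.n_states_}")

    def random_hidden_state(self, seed: int | None = None) -> np.ndarray:
        """Uniform(-0.5, 0.5)^N initial hidden state."""
        self._check_fitted()
        rng = np.random.default_rng(seed)
        return rng.uniform(-0.5, 0.5, size=self.weights_.params.N)

    def recall(
        self,
        i: int,
        n_steps: int = 10000,
        seed: int | None = 0,
        settle_steps: int = 1000,
        r0: np.ndarray | None = None,
    ) -> GenerationResult:
        """Retrieve stored state ``i`` by its index code.

        Starts from a random (seeded) hidden state, lets the closed loop
        settle, then generates ``n_steps`` of output.
        """
        self._check_fitted()
        self._check_state(i)
        if r0 is None:
            r0 = self.random_hidden_state(seed)
        p = self._code(i)
        settle = closed_loop(self.weights_, p=p, r0=r0, n_steps=max(settle_steps, 1))
        if settle.diverged:
            return settle
        v_last = settle.trajectory.values[-1]
        out = closed_loop(
            self.weights_, p=p, r0=settle.r_final, n_steps=n_steps, v0=v_last,
            dt=self.library_.trajectories[i - 1].dt,
        )
        return out

    def warm_recall(
        self,
        i: int,
        cue: Trajectory | np.ndarray,
        n_steps: int = 2000,
        r0: np.ndarray | None = None,
        seed: int | None = 0,
    ) -> GenerationResult:
        """Warm up with a cue signal (open loop at p_i), then run closed loop."""
        self._check_fitted()
        self._check_state(i)
        if r0 is None:
            r0 = self.random_hidden_state(seed)
        p = self._code(i)
        r = warmup(self.weights_, cue, p=p, r0=r0)
        cue_vals = cue.values if isinstance(cue, Trajectory) else np.asarray(cue)
        v0 = cue_vals[-1] if len(cue_vals) else None
        return closed_loop(self.weights_, p=p, r0=r, n_steps=n_steps, v0=v0)

    def switch_index(
        self,
        j: int,
        r_last: np.ndarray,
        v_last: np.ndarray,
        n_steps: int = 200,
    ) -> GenerationResult:
        """Continue closed-loop under the code of state ``j`` from an
        inherited hidden state and output — the elementary index switch."""
        self._check_fitted()
        self._check_state(j)
        return closed_loop(self.weights_, p=self._code(j), r0=r_last, n_steps=n_steps, v0=v_last)

    def run_on_state(
        self, i: int, n_steps: int, seed: int | None = 0
    ) -> GenerationResult:
        """Closed-loop run settled onto stored state ``i`` (recall shorthand)."""
        return self.recall(i, n_steps=n_steps, seed=seed)


def train_memory(library: AttractorLibrary, params: ReservoirParams | None = None, **kw) -> ReservoirMemory:
    """Functional wrapper: fit a :class:`ReservoirMemory` on a library."""
    if params is not None:
        kw = dict(
            N=params.N,
            spectral_radius=params.spectral_radius,
            density=params.density,
            input_scale=params.input_scale,
            index_scale=params.index_scale,
            bias_scale=params.bias_scale,
            leak=params.leak,
            ridge_beta=params.ridge_beta,
            readout_features=params.readout_features,
            washout=params.washout,
            guard_factor=params.guard_factor,
            seed=params.seed,
            **kw,
        )
    return ReservoirMemory(**kw).fit(library)


def train_indexfree(library: AttractorLibrary, **kw) -> ReservoirMemory:
    """Fit a content-addressable memory: same batch training, no index
    channel; the stored attractors become coexisting closed-loop states."""
    stripped = AttractorLibrary(
        trajectories=library.trajectories, coding=None, names=library.names
    )
    return ReservoirMemory(**kw).fit(stripped)


def train_separate_readouts(
    library: AttractorLibrary, **kw
) -> tuple[ReservoirMemory, list[np.ndarray]]:
    """Shared input and hidden layer, one ridge readout per attractor.

    Returns the fitted memory (its ``weights_.W_out`` is the pooled readout)
    plus the per-attractor readouts. Retrieval under this variant selects the
    matching W_out before running closed-loop.
    """
    mem = ReservoirMemory(**kw)
    library = library if isinstance(library, AttractorLibrary) else AttractorLibrary.from_trajectories(library)
    params = mem._make_params(library)
    rc = init_reservoir(params)
    mem.library_ = library
    pooled = RidgeAccumulator(params.n_features, library.n_dims)
    per_state: list[np.ndarray] = []
    amp = 0.0
    for _i, _p, feats, targets in mem._driven_segments(rc, library):
        solo = RidgeAccumulator(params.n_features, library.n_dims)
        solo.add(feats, targets)
        per_state.append(solo.solve(mem.ridge_beta))
        pooled.add(feats, targets)
        amp = max(amp, float(np.max(np.abs(targets))))
    rc.W_out = pooled.solve(mem.ridge_beta)
    rc.guard_bound = mem.guard_factor * amp
    mem.weights_ = rc
    mem.n_states_ = library.K
    mem.n_dims_ = library.n_dims
    return mem, per_state
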