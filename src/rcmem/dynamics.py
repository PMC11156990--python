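"""Target dynamical states: ODE integration, explicit curves, normalization.

Every pattern stored in a reservoir memory is a :class:`Trajectory` — a
uniformly sampled multivariate time series. This module generates them by
fixed-step RK4 integration of a registry of named vector fields (Lorenz,
Rössler, a three-species food chain, Hindmarsh–Rose, the Sprott flows),
by closed-form periodic curves (Lissajous, random Fourier-series loops),
and normalizes them to zero mean and unit standard deviation per dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "SystemSpec",
    "SYSTEMS",
    "integrate_system",
    "normalize",
    "denormalize",
    "lissajous",
    "fourier_attractor",
    "average_period",
    "bifurcation_library",
]


# ---------------------------------------------------------------------------
# Trajectory container


@dataclass
class Trajectory:
    """A uniformly sampled multivariate time series.

    Parameters
    ----------
    values : ndarray of shape (T, D)
        State samples, one row per time step.
    dt : float
        Sampling step in system time units.
    name : str
        Human-readable label (system name, dataset id, ...).
    is_periodic : bool or None
        Whether the series is (meant to be) periodic.
    period_steps : float or None
        Period, or average period for chaotic states, in sampling steps.
    mean, scale : ndarray or None
        If the trajectory was produced by :func:`normalize`, the affine
        transform ``original = normalized * scale + mean`` for inverse
        mapping.
    """

    values: np.ndarray
    dt: float = 1.0
    name: str = ""
    is_periodic: bool | None = None
    period_steps: float | None = None
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be a (T, D) matrix")
        if self.values.shape[0] < 2:
            raise ValueError("a trajectory needs at least two samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trajectory {self.name!r} contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    def segment(self, start: int, stop: int) -> "Trajectory":
        """A view-backed sub-trajectory covering ``values[start:stop]``."""
        return replace(self, values=self.values[start:stop])


# ---------------------------------------------------------------------------
# Vector-field registry
#
# Each field maps a state array of shape (..., D) to its time derivative with
# the same shape, broadcasting over leading axes so that ensembles of initial
# conditions (or of parameter values) integrate in one vectorized sweep.


def _lorenz(s, p):
    x, y, z = s[..., 0], s[..., 1], s[..., 2]
    return np.stack(
        [p["sigma"] * (y - x), x * (p["rho"] - z) - y, x * y - p["beta"] * z],
        axis=-1,
    )


def _rossler(s, p):
    x, y, z = s[..., 0], s[..., 1], s[..., 2]
    return np.stack([-y - z, x + p["a"] * y, p["b"] + z * (x - p["c"])], axis=-1)


def _foodchain(s, p):
    """Three-species resource–consumer–predator chain with logistic resource
    growth (carrying capacity ``K_f``) and Holling type-II functional
    responses."""
    R, C, P = s[..., 0], s[..., 1], s[..., 2]
    xc, yc, xp, yp = p["x_c"], p["y_c"], p["x_p"], p["y_p"]
    R0, C0 = p["R0"], p["C0"]
    dR = R * (1.0 - R / p["K_f"]) - xc * yc * C * R / (R + R0)
    dC = xc * C * (yc * R / (R + R0) - 1.0) - xp * yp * P * C / (C + C0)
    dP = xp * P * (yp * C / (C + C0) - 1.0)
    return np.stack([dR, dC, dP], axis=-1)


def _hindmarsh_rose(s, p):
    x, y, z = s[..., 0], s[..., 1], s[..., 2]
    dx = y - p["a"] * x**3 + p["b"] * x**2 - z + p["I"]
    dy = p["c"] - p["d"] * x**2 - y
    dz = p["r"] * (p["s"] * (x - p["x0"]) - z)
    return np.stack([dx, dy, dz], axis=-1)


def _make_sprott(fx, fy, fz):
    def f(s, p):
        x, y, z = s[..., 0], s[..., 1], s[..., 2]
        return np.stack([fx(x, y, z), fy(x, y, z), fz(x, y, z)], axis=-1)

    return f


# The nineteen canonical three-dimensional quadratic chaotic flows A..S.
_SPROTT_FIELDS = {
    "a": _make_sprott(lambda x, y, z: y, lambda x, y, z: -x + y * z, lambda x, y, z: 1 - y**2),
    "b": _make_sprott(lambda x, y, z: y * z, lambda x, y, z: x - y, lambda x, y, z: 1 - x * y),
    "c": _make_sprott(lambda x, y, z: y * z, lambda x, y, z: x - y, lambda x, y, z: 1 - x**2),
    "d": _make_sprott(lambda x, y, z: -y, lambda x, y, z: x + z, lambda x, y, z: x * z + 3 * y**2),
    "e": _make_sprott(lambda x, y, z: y * z, lambda x, y, z: x**2 - y, lambda x, y, z: 1 - 4 * x),
    # F carries its damping coefficient as a parameter: a=0.5 is the canonical
    # chaotic flow; a<=0.25 settles onto a stable limit cycle.
    "f": lambda s, p: np.stack(
        [
            s[..., 1] + s[..., 2],
            -s[..., 0] + p.get("a", 0.5) * s[..., 1],
            s[..., 0] ** 2 - s[..., 2],
        ],
        axis=-1,
    ),
    "g": _make_sprott(lambda x, y, z: 0.4 * x + z, lambda x, y, z: x * z - y, lambda x, y, z: -x + y),
    "h": _make_sprott(lambda x, y, z: -y + z**2, lambda x, y, z: x + 0.5 * y, lambda x, y, z: x - z),
    "i": _make_sprott(lambda x, y, z: -0.2 * y, lambda x, y, z: x + z, lambda x, y, z: x + y**2 - z),
    "j": _make_sprott(lambda x, y, z: 2 * z, lambda x, y, z: -2 * y + z, lambda x, y, z: -x + y + y**2),
    "k": _make_sprott(lambda x, y, z: x * y - z, lambda x, y, z: x - y, lambda x, y, z: x + 0.3 * z),
    "l": _make_sprott(lambda x, y, z: y + 3.9 * z, lambda x, y, z: 0.9 * x**2 - y, lambda x, y, z: 1 - x),
    "m": _make_sprott(lambda x, y, z: -z, lambda x, y, z: -(x**2) - y, lambda x, y, z: 1.7 + 1.7 * x + y),
    "n": _make_sprott(lambda x, y, z: -2 * y, lambda x, y, z: x + z**2, lambda x, y, z: 1 + y - 2 * z),
    "o": _make_sprott(lambda x, y, z: y, lambda x, y, z: x - z, lambda x, y, z: x + x * z + 2.7 * y),
    "p": _make_sprott(lambda x, y, z: 2.7 * y + z, lambda x, y, z: -x + y**2, lambda x, y, z: x + y),
    "q": _make_sprott(lambda x, y, z: -z, lambda x, y, z: x - y, lambda x, y, z: 3.1 * x + y**2 + 0.5 * z),
    "r": _make_sprott(lambda x, y, z: 0.9 - y, lambda x, y, z: 0.4 + z, lambda x, y, z: x * y - z),
    "s": _make_sprott(lambda x, y, z: -x - 4 * y, lambda x, y, z: x + z**2, lambda x, y, z: 1 + x),
}


@dataclass
class _SystemDef:
    field_fn: Callable[[np.ndarray, dict], np.ndarray]
    default_params: dict
    ic_low: np.ndarray
    ic_high: np.ndarray


def _sysdef(field_fn, params, low, high):
    return _SystemDef(field_fn, dict(params), np.asarray(low, float), np.asarray(high, float))


SYSTEMS: dict[str, _SystemDef] = {
    "lorenz": _sysdef(
        _lorenz, {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0}, [-8, -8, 20], [8, 8, 30]
    ),
    "rossler": _sysdef(_rossler, {"a": 0.2, "b": 0.2, "c": 5.7}, [-6, -6, 0], [6, 0, 2]),
    "foodchain": _sysdef(
        _foodchain,
        {
            "K_f": 0.99,
            "x_c": 0.4,
            "y_c": 2.009,
            "x_p": 0.08,
            "y_p": 2.876,
            "R0": 0.16129,
            "C0": 0.5,
        },
        [0.5, 0.2, 0.6],
        [0.9, 0.4, 1.0],
    ),
    "hindmarsh_rose": _sysdef(
        _hindmarsh_rose,
        {"a": 1.0, "b": 3.0, "c": 1.0, "d": 5.0, "s": 4.0, "x0": -1.6, "r": 0.006, "I": 3.25},
        [-1.2, -6.0, 2.8],
        [0.5, 0.0, 3.4],
    ),
}
for _letter, _f in _SPROTT_FIELDS.items():
    SYSTEMS[f"sprott_{_letter}"] = _sysdef(_f, {}, [0.0, 0.0, 0.0], [0.1, 0.1, 0.1])
SYSTEMS["sprott_f"].default_params = {"a": 0.5}


@dataclass
class SystemSpec:
    """Recipe for producing a sampled trajectory of a named ODE system.

    ``integrate_dt`` is the RK4 step; every ``sample_every``-th integration
    step is kept, so the output sampling step is
    ``dt = integrate_dt * sample_every * time_scale`` in rescaled time.
    ``time_scale`` multiplies the vector field, uniformly speeding up or
    slowing down the flow so that attractors with very different natural
    time scales can be brought to a comparable number of steps per
    oscillation cycle.
    """

    system_id: str
    params: dict = field(default_factory=dict)
    integrate_dt: float = 0.01
    sample_every: int = 10
    transient_steps: int = 1000
    time_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.system_id not in SYSTEMS:
            raise ValueError(
                f"unknown system_id {self.system_id!r}; known: {sorted(SYSTEMS)}"
            )
        if self.integrate_dt <= 0 or self.sample_every < 1 or self.transient_steps < 0:
            raise ValueError("invalid integration settings")
        merged = dict(SYSTEMS[self.system_id].default_params)
        merged.update(self.params)
        self.params = merged

    @property
    def dt(self) -> float:
        return self.integrate_dt * self.sample_every


class DivergenceError(RuntimeError):
    """Raised when an integration blows up; carries the failing step index."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"non-finite state at integration step {step}")


_DIVERGENCE_BOUND = 1e6


def _rk4_sweep(field_fn, params, state, dt, n_substeps):
    """Advance ``state`` (shape (..., D)) by ``n_substeps`` RK4 steps."""
    for _ in range(n_substeps):
        k1 = field_fn(state, params)
        k2 = field_fn(state + 0.5 * dt * k1, params)
        k3 = field_fn(state + 0.5 * dt * k2, params)
        k4 = field_fn(state + dt * k3, params)
        state = state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return state


def integrate_batch(
    spec: SystemSpec, n_steps: int, x0: np.ndarray
) -> np.ndarray:
    """Integrate from a batch of initial conditions.

    Parameters
    ----------
    x0 : ndarray of shape (B, D) or (D,)
        Initial condition(s) *after* any transient handling by the caller.

    Returns
    -------
    ndarray of shape (n_steps, B, D) (or (n_steps, D) for a single state):
        sampled states, the first sample being ``x0`` itself.
    """
    sysdef = SYSTEMS[spec.system_id]
    params = spec.params
    dt = spec.integrate_dt
    if spec.time_scale != 1.0:
        base = sysdef.field_fn
        ts = spec.time_scale
        field_fn = lambda s, p: ts * base(s, p)  # noqa: E731
    else:
        field_fn = sysdef.field_fn
    state = np.asarray(x0, dtype=float)
    out = np.empty((n_steps,) + state.shape, dtype=float)
    out[0] = state
    for t in range(1, n_steps):
        state = _rk4_sweep(field_fn, params, state, dt, spec.sample_every)
        if not np.all(np.isfinite(state)) or np.max(np.abs(state)) > _DIVERGENCE_BOUND:
            raise DivergenceError(t * spec.sample_every)
        out[t] = state
    return out


def integrate_system(spec: SystemSpec, n_steps: int, seed: int = 0) -> Trajectory:
    """Integrate a named system from a seeded random initial condition.

    The initial condition is drawn uniformly from a per-system bounding box
    near the attractor, a transient of ``spec.transient_steps`` sampled steps
    is discarded, and ``n_steps`` samples are returned. Deterministic given
    ``(spec, n_steps, seed)``.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if spec.system_id == "lissajous":  # pragma: no cover - guarded in SystemSpec
        raise ValueError("use lissajous() for explicit curves")
    sysdef = SYSTEMS[spec.system_id]
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(sysdef.ic_low, sysdef.ic_high)
    total = spec.transient_steps + n_steps
    states = integrate_batch(spec, total, x0)
    return Trajectory(
        values=states[spec.transient_steps :],
        dt=spec.dt,
        name=spec.system_id,
    )


# ---------------------------------------------------------------------------
# Explicit periodic curves


def lissajous(
    n_steps: int,
    period_steps: float = 40.0,
    freqs: Sequence[int] = (1, 2, 3),
    phases: Sequence[float] = (0.0, np.pi / 4, np.pi / 2),
    dt: float = 0.1,
) -> Trajectory:
    """A three-dimensional Lissajous curve, exactly periodic in steps."""
    t = np.arange(n_steps)
    omega = 2.0 * np.pi / period_steps
    cols = [np.sin(f * omega * t + ph) for f, ph in zip(freqs, phases)]
    return Trajectory(
        values=np.stack(cols, axis=-1),
        dt=dt,
        name="lissajous",
        is_periodic=True,
        period_steps=float(period_steps),
    )


def _fourier_design(phases: np.ndarray, order: int, period: float) -> np.ndarray:
    omega = 2.0 * np.pi / period
    cols = [np.ones_like(phases)]
    for m in range(1, order + 1):
        cols.append(np.cos(m * omega * phases))
        cols.append(np.sin(m * omega * phases))
    return np.stack(cols, axis=-1)


def fourier_attractor(
    seed: int,
    dims: int = 3,
    period_steps: int = 200,
    order: int = 4,
    n_points_range: tuple[int, int] = (2, 5),
    n_steps: int | None = None,
    max_retries: int = 20,
) -> Trajectory:
    """A random smooth periodic curve: per dimension, a low-order Fourier
    series passed through a handful of random control points.

    For each dimension independently, ``k`` control points (``k`` uniform in
    ``n_points_range``) are placed at random phases within one period with
    ordinates uniform in [-1, 1]; the minimum-norm least-squares Fourier fit
    of the given order interpolates them and is evaluated at integer steps,
    giving a curve with exact discrete period ``period_steps``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if period_steps < 4 * order:
        raise ValueError("period_steps must be at least 4*order")
    if n_steps is None:
        n_steps = period_steps
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps, dtype=float)
    design_t = _fourier_design(t, order, period_steps)
    values = np.empty((n_steps, dims))
    for d in range(dims):
        for attempt in range(max_retries):
            k = int(rng.integers(n_points_range[0], n_points_range[1] + 1))
            phases = rng.uniform(0.0, period_steps, size=k)
            targets = rng.uniform(-1.0, 1.0, size=k)
            design = _fourier_design(phases, order, period_steps)
            coef, _, rank, _ = np.linalg.lstsq(design, targets, rcond=None)
            if rank == min(design.shape) and np.all(np.isfinite(coef)):
                values[:, d] = design_t @ coef
                break
        else:
            raise RuntimeError(
                f"could not fit a nondegenerate Fourier curve for dimension {d}"
            )
    return Trajectory(
        values=values,
        dt=1.0,
        name=f"fourier[{seed}]",
        is_periodic=True,
        period_steps=float(period_steps),
    )


# ---------------------------------------------------------------------------
# Normalization


def normalize(traj: Trajectory) -> Trajectory:
    """Rescale each dimension to zero mean and unit (population) standard
    deviation, keeping the affine transform for inverse mapping."""
    mu = traj.values.mean(axis=0)
    sd = traj.values.std(axis=0)  # ddof=0: population convention
    bad = np.nonzero(sd < 1e-15)[0]
    if bad.size:
        raise ValueError(f"constant dimension(s) {bad.tolist()} cannot be normalized")
    # compose with any existing transform so denormalize always recovers raw data
    if traj.mean is not None:
        mean = traj.mean + traj.scale * mu
        scale = traj.scale * sd
    else:
        mean, scale = mu, sd
    return replace(traj, values=(traj.values - mu) / sd, mean=mean, scale=scale)


def denormalize(traj: Trajectory) -> Trajectory:
    """Invert :func:`normalize` using the stored affine transform."""
    if traj.mean is None or traj.scale is None:
        raise ValueError("trajectory carries no normalization transform")
    return replace(traj, values=traj.values * traj.scale + traj.mean, mean=None, scale=None)


# ---------------------------------------------------------------------------
# Period estimation


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus credited to their first index."""
    idx = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def average_period(traj: Trajectory, dim: int = 0) -> float:
    """Mean interval, in steps, between successive local maxima of one
    dimension — the average (oscillation) period, also defined for chaotic
    states."""
    x = traj.values[:, dim]
    maxima = _local_maxima(x)
    if maxima.size < 2:
        raise ValueError("need at least two local maxima to estimate a period")
    return float(np.mean(np.diff(maxima)))


# ---------------------------------------------------------------------------
# Bifurcation-sweep library (food chain)


def bifurcation_library(
    n_states: int = 100,
    kf_range: tuple[float, float] = (0.92, 1.0),
    n_steps: int = 2000,
    transient_time: float = 2000.0,
    seed: int = 0,
    index_range: tuple[float, float] = (-2.5, 2.5),
):
    """States of the food-chain system at ``n_states`` evenly spaced carrying
    capacities ``K_f``, sampled at dt = 1, with scalar index values evenly
    spaced on ``index_range`` and ordered by ``K_f``.

    Returns an :class:`rcmem.coding.AttractorLibrary` with a scalar coding.
    """
    from .coding import AttractorLibrary, IndexCoding

    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    kfs = np.linspace(kf_range[0], kf_range[1], n_states)
    spec = SystemSpec("foodchain", integrate_dt=0.02, sample_every=50)  # dt = 1
    rng = np.random.default_rng(seed)
    sysdef = SYSTEMS["foodchain"]
    field_fn = sysdef.field_fn

    def sweep(kf_subset, transient):
        x0 = rng.uniform(sysdef.ic_low, sysdef.ic_high, size=(len(kf_subset), 3))
        params = dict(spec.params)
        params["K_f"] = kf_subset  # broadcasts over the batch
        state = x0
        n_transient = int(round(transient / spec.dt))
        out = np.empty((n_steps, len(kf_subset), 3))
        for t in range(n_transient + n_steps):
            state = _rk4_sweep(field_fn, params, state, spec.integrate_dt, spec.sample_every)
            if not np.all(np.isfinite(state)):
                bad = int(np.nonzero(~np.isfinite(state).all(axis=-1))[0][0])
                raise DivergenceError(t, f"divergent integration at K_f={kf_subset[bad]:.4f}")
            if t >= n_transient:
                out[t - n_transient] = state
        return out

    out = sweep(kfs, transient_time)
    # Near the top of the sweep interval the chaotic set loses stability
    # (boundary crisis): the predator can go extinct, collapsing a dimension.
    # Retry such states from fresh initial conditions with a short transient,
    # which samples the long chaotic transient instead of the dead state.
    tail = max(2, n_steps // 4)
    for _attempt in range(6):
        stds = out[-tail:].std(axis=0).min(axis=1)  # flat tail = collapsed state
        bad = np.nonzero(stds < 1e-6)[0]
        if bad.size == 0:
            break
        out[:, bad] = sweep(kfs[bad], 200.0)
    else:
        worst = kfs[int(np.argmin(out[-tail:].std(axis=0).min(axis=1)))]
        raise DivergenceError(0, f"state collapsed at K_f={worst:.4f}")
    trajs = [
        normalize(Trajectory(out[:, i], dt=1.0, name=f"foodchain[K_f={kfs[i]:.4f}]"))
        for i in range(n_states)
    ]
    codes = np.linspace(index_range[0], index_range[1], n_states)[:, None]
    coding = IndexCoding(scheme="scalar", K=n_states, codes=codes)
    return AttractorLibrary(
        trajectories=trajs,
        coding=coding,
        names=[t.name for t in trajs],
    )
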