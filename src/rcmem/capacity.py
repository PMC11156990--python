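"""Memory-capacity scaling: how large a reservoir is needed to store K
attractors.

For a fixed (K, N) pair an ensemble of reservoirs is trained; each stored
state is validated by warm-starting on its reference series and scoring the
closed-loop continuation with one of three measures (prediction horizon,
windowed RMSE, region escape). A network counts as successful when every
stored state passes, the success rate is the ensemble fraction, the
critical size N_c is the grid point whose rate is closest to 50%, and the
capacity law is the power-law fit N_c ∝ K^gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import AttractorLibrary
from .dynamics import Trajectory, average_period
from .memory import ReservoirMemory, train_separate_readouts
from .metrics import (
    oscillation_amplitude,
    prediction_horizon,
    region_escape_time,
    rmse_window,
)
from .reservoir import closed_loop, drive

__all__ = [
    "ValidationThresholds",
    "validate_network",
    "success_rate_curve",
    "extract_Nc",
    "fit_power_law",
    "ScalingResult",
    "run_task",
]

MEASURES = ("prediction_horizon", "rmse", "region_escape")


@dataclass
class ValidationThresholds:
    """Fixed per-task success thresholds for the three recall measures.

    ``horizon_periods``: minimum prediction horizon, in (average) periods.
    ``rmse_max``: maximum RMSE over a four-period validation window
    (targets are z-normalized, so an O(1) error means a lost attractor).
    ``region_periods``: minimum time, in periods, spent inside the 10%-
    inflated bounding box of the memory state.
    """

    horizon_periods: float = 2.0
    rmse_max: float = 0.3
    region_periods: float = 4.0
    rmse_window_periods: float = 4.0


def validate_network(
    mem: ReservoirMemory,
    thresholds: ValidationThresholds = ValidationThresholds(),
    warm_steps: int = 100,
    per_state_readouts: list[np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Score every stored state of a fitted memory with all three measures.

    Each state is warm-started on a segment of its reference series and the
    closed-loop continuation is compared against the actual continuation.
    Returns per-measure boolean pass vectors over the K states.
    """
    lib = mem.library_
    K = lib.K
    passes = {m: np.zeros(K, dtype=bool) for m in MEASURES}
    for i in range(1, K + 1):
        traj = lib.trajectories[i - 1]
        u = traj.values
        period = traj.period_steps or average_period(traj, 0)
        horizon_steps = int(round(thresholds.region_periods * period)) + 10
        window_steps = int(round(thresholds.rmse_window_periods * period))
        n_gen = max(horizon_steps, window_steps)
        if warm_steps + n_gen + 1 > len(u):
            raise ValueError("reference series too short for validation")
        rc = mem.weights_
        if per_state_readouts is not None:
            import copy

            rc = copy.copy(rc)
            rc.W_out = per_state_readouts[i - 1]
        p = mem._code(i)
        states = drive(rc, u[:warm_steps], p=p)
        res = closed_loop(rc, p=p, r0=states[-1], v0=u[warm_steps], n_steps=n_gen)
        pred = res.trajectory.values
        truth = u[warm_steps + 1 : warm_steps + 1 + n_gen]
        hor = prediction_horizon(pred, truth, period, reference=u)
        passes["prediction_horizon"][i - 1] = hor >= thresholds.horizon_periods
        rmse = rmse_window(pred, truth, period, thresholds.rmse_window_periods)
        passes["rmse"][i - 1] = rmse <= thresholds.rmse_max
        box = (u.min(axis=0), u.max(axis=0))
        esc = region_escape_time(pred, box)
        passes["region_escape"][i - 1] = esc >= thresholds.region_periods * period
    return passes


def success_rate_curve(
    library_factory,
    K: int,
    N_grid: tuple[int, ...],
    ensemble_size: int = 8,
    seed: int = 0,
    thresholds: ValidationThresholds = ValidationThresholds(),
    separate_readouts: bool = False,
    mem_kwargs: dict | None = None,
) -> dict[str, np.ndarray]:
    """Fraction of trained networks whose stored states *all* pass each
    measure, over a grid of reservoir sizes.

    ``library_factory(K, seed)`` supplies the K-state library; a fresh
    library and reservoir seed is drawn per ensemble member.
    """
    mem_kwargs = dict(mem_kwargs or {})
    rng = np.random.default_rng(seed)
    rates = {m: np.zeros(len(N_grid)) for m in MEASURES}
    for k, N in enumerate(N_grid):
        wins = {m: 0 for m in MEASURES}
        for e in range(ensemble_size):
            lib = library_factory(K, int(rng.integers(2**31 - 1)))
            kw = dict(mem_kwargs)
            kw["N"] = int(N)
            kw["seed"] = int(rng.integers(2**31 - 1))
            if separate_readouts:
                mem, per_state = train_separate_readouts(lib, **kw)
                passes = validate_network(mem, thresholds, per_state_readouts=per_state)
            else:
                mem = ReservoirMemory(**kw).fit(lib)
                passes = validate_network(mem, thresholds)
            for m in MEASURES:
                wins[m] += bool(passes[m].all())
        for m in MEASURES:
            rates[m][k] = wins[m] / ensemble_size
    return rates


def extract_Nc(
    N_grid: tuple[int, ...] | np.ndarray,
    rates: np.ndarray,
    threshold: float = 0.5,
) -> int:
    """Critical reservoir size: the grid point whose success rate is closest
    to the threshold (ties resolve toward the smaller N).

    The curve must actually span the threshold; otherwise the grid cannot
    locate N_c and a wider grid is required.
    """
    N_grid = np.asarray(N_grid)
    rates = np.asarray(rates, dtype=float)
    if N_grid.shape != rates.shape:
        raise ValueError("N_grid and rates must align")
    if rates.min() > threshold or rates.max() < threshold:
        raise ValueError(
            f"success-rate curve does not cross {threshold}; widen the N grid "
            f"(rates span [{rates.min():.2f}, {rates.max():.2f}])"
        )
    order = np.argsort(N_grid)
    N_sorted, r_sorted = N_grid[order], rates[order]
    # candidates: the pair bracketing the (last) upward threshold crossing,
    # so that a steep 0 -> 1 jump cannot alias to a far-away tied grid point
    above = np.nonzero(r_sorted >= threshold)[0]
    first_above = above[0]
    lo = max(0, first_above - 1)
    dist = np.abs(r_sorted[lo : first_above + 1] - threshold)
    return int(N_sorted[lo + np.argmin(dist)])  # ties resolve toward smaller N


def fit_power_law(
    K_values, N_c_values
) -> tuple[float, float, float]:
    """Least-squares fit of log N_c = gamma log K + c.

    Returns (gamma, intercept c, standard error of gamma).
    """
    K = np.asarray(K_values, dtype=float)
    Nc = np.asarray(N_c_values, dtype=float)
    if len(K) < 3:
        raise ValueError("need at least three (K, N_c) pairs")
    if np.any(K <= 0) or np.any(Nc <= 0):
        raise ValueError("K and N_c must be positive")
    x, y = np.log(K), np.log(Nc)
    coef, cov = np.polyfit(x, y, 1, cov=True)
    gamma, intercept = float(coef[0]), float(coef[1])
    se = float(np.sqrt(cov[0, 0]))
    return gamma, intercept, se


@dataclass
class ScalingResult:
    """Product of one capacity-scaling task."""

    task: str
    coding: str | None
    K_values: list[int]
    N_grids: dict[int, list[int]]
    success_rates: dict[int, dict[str, list[float]]]
    N_c: dict[str, dict[int, int]] = field(default_factory=dict)
    gamma: dict[str, float] = field(default_factory=dict)
    gamma_se: dict[str, float] = field(default_factory=dict)

    def fit(self, measure: str = "region_escape") -> None:
        Ks, Ncs = [], []
        self.N_c.setdefault(measure, {})
        for K in self.K_values:
            nc = extract_Nc(self.N_grids[K], np.asarray(self.success_rates[K][measure]))
            self.N_c[measure][K] = nc
            Ks.append(K)
            Ncs.append(nc)
        gamma, _c, se = fit_power_law(Ks, Ncs)
        self.gamma[measure] = gamma
        self.gamma_se[measure] = se


def _dataset1_factory(dims: int = 3, n_steps: int = 1500, coding: str = "one_hot"):
    from .io import dataset1_library

    def factory(K: int, seed: int) -> AttractorLibrary:
        return dataset1_library(K, seed=seed, dims=dims, n_steps=n_steps, coding=coding)

    return factory


def _bifurcation_factory(n_steps: int = 1200, transient_time: float = 500.0):
    from .dynamics import bifurcation_library

    def factory(K: int, seed: int) -> AttractorLibrary:
        return bifurcation_library(K, n_steps=n_steps, transient_time=transient_time, seed=seed)

    return factory


def _synthetic_videos_factory(n_steps: int = 1500):
    """Stand-in for a rotating-objects video task: two-dimensional periodic
    states (period 36 steps) from random low-order Fourier loops. Synthetic:
    no real video data is involved."""
    from .dynamics import fourier_attractor, normalize

    def factory(K: int, seed: int) -> AttractorLibrary:
        rng = np.random.default_rng(seed)
        trajs = [
            normalize(
                fourier_attractor(int(s), dims=2, period_steps=36, order=4, n_steps=n_steps)
            )
            for s in rng.integers(0, 2**31 - 1, size=K)
        ]
        return AttractorLibrary.from_trajectories(trajs, scheme="one_hot")

    return factory


_TASKS = {
    "onehot": dict(factory=lambda: _dataset1_factory(coding="one_hot"), coding="one_hot"),
    "binary": dict(factory=lambda: _dataset1_factory(coding="binary"), coding="binary"),
    "kd2": dict(factory=lambda: _dataset1_factory(coding="kd_integer"), coding="kd_integer"),
    "separate_wout": dict(
        factory=lambda: _dataset1_factory(coding="one_hot"), coding="one_hot", separate=True
    ),
    "bifurcation": dict(factory=_bifurcation_factory, coding="scalar"),
    "indexfree": dict(factory=lambda: _dataset1_factory(coding=None), coding=None),
    "synthetic_videos": dict(factory=_synthetic_videos_factory, coding="one_hot"),
}


def run_task(
    task: str,
    K_values: tuple[int, ...] = (2, 4, 8, 16, 32),
    N_grids: dict[int, tuple[int, ...]] | None = None,
    ensemble_size: int = 8,
    seed: int = 0,
    mem_kwargs: dict | None = None,
    measures: tuple[str, ...] = MEASURES,
) -> ScalingResult:
    """Run one named capacity task end to end: success curves per K, N_c
    extraction at the 50% threshold, and the power-law fit, for each measure.

    ``N_grids`` maps each K to its reservoir-size grid; when omitted, a
    geometric default grid proportional to K is used.
    """
    if task not in _TASKS:
        raise ValueError(f"unknown task {task!r}; known: {sorted(_TASKS)}")
    cfg = _TASKS[task]
    factory = cfg["factory"]()
    if N_grids is None:
        N_grids = {
            K: tuple(int(round(K * f)) for f in (4, 8, 16, 32, 64)) for K in K_values
        }
    result = ScalingResult(
        task=task,
        coding=cfg["coding"],
        K_values=list(K_values),
        N_grids={K: list(map(int, N_grids[K])) for K in K_values},
        success_rates={},
    )
    rng = np.random.default_rng(seed)
    for K in K_values:
        rates = success_rate_curve(
            factory,
            K,
            tuple(N_grids[K]),
            ensemble_size=ensemble_size,
            seed=int(rng.integers(2**31 - 1)),
            separate_readouts=cfg.get("separate", False),
            mem_kwargs=mem_kwargs,
        )
        result.success_rates[K] = {m: list(map(float, rates[m])) for m in MEASURES}
    for m in measures:
        try:
            result.fit(m)
        except ValueError:
            # curve did not bracket the threshold for some K; leave unfitted
            continue
    return result
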