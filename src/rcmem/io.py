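"""Serialization, trajectory I/O, and the standard attractor libraries.

Models are stored as a single ``.npz`` container (all weight arrays plus a
JSON header with hyperparameters and bookkeeping); trajectories as CSV with
a header row of dimension names. Round trips are bit-exact, so closed-loop
outputs from a reloaded model match the original run exactly.
"""

from __future__ import annotations

import io as _stdio
import json
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .coding import AttractorLibrary, IndexCoding, make_coding
from .dynamics import (
    SystemSpec,
    Trajectory,
    fourier_attractor,
    integrate_system,
    lissajous,
    normalize,
    bifurcation_library,
)
from .memory import ReservoirMemory
from .reservoir import ReservoirParams, ReservoirWeights

__all__ = [
    "save_model",
    "load_model",
    "save_trajectory_csv",
    "load_trajectory_csv",
    "six_attractor_library",
    "sprott16_library",
    "dataset1_library",
    "make_fixture",
]


# ---------------------------------------------------------------------------
# Trajectory CSV I/O


def save_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    header = ",".join(f"dim{i}" for i in range(traj.n_dims))
    meta = json.dumps(
        {
            "dt": traj.dt,
            "name": traj.name,
            "is_periodic": traj.is_periodic,
            "period_steps": traj.period_steps,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# {meta}\n{header}\n")
        np.savetxt(fh, traj.values, delimiter=",")


def load_trajectory_csv(path: str | Path) -> Trajectory:
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first[1:].strip()) if first.startswith("#") else {}
        rest = fh.read()
    values = np.loadtxt(_stdio.StringIO(rest), delimiter=",", skiprows=1)
    return Trajectory(
        values=np.atleast_2d(values),
        dt=float(meta.get("dt", 1.0)),
        name=meta.get("name", ""),
        is_periodic=meta.get("is_periodic"),
        period_steps=meta.get("period_steps"),
    )


# ---------------------------------------------------------------------------
# Model serialization


class ModelFormatError(ValueError):
    """Wrong or corrupt model container."""


def _estimator_payload(est) -> dict:
    from .classify import ReservoirClassifier

    if isinstance(est, ReservoirMemory):
        kind = "memory"
    elif isinstance(est, ReservoirClassifier):
        kind = "classifier"
    else:
        raise TypeError(f"cannot serialize object of type {type(est).__name__}")
    return {"kind": kind, "init_params": est.get_params()}


def save_model(est, path: str | Path) -> None:
    """Save a fitted ReservoirMemory or ReservoirClassifier losslessly."""
    rc: ReservoirWeights = est.weights_
    header = _estimator_payload(est)
    header["reservoir_params"] = rc.params.__dict__
    header["guard_bound"] = rc.guard_bound
    arrays = {
        "W_in": rc.W_in,
        "W_index": rc.W_index,
        "bias": rc.bias,
        "A_data": rc.A.data,
        "A_indices": rc.A.indices,
        "A_indptr": rc.A.indptr,
        "W_out": rc.W_out if rc.W_out is not None else np.zeros((0, 0)),
    }
    if header["kind"] == "classifier":
        header["classes"] = [int(c) for c in est.classes_]
    else:
        lib = est.library_
        header["library"] = {
            "names": lib.names,
            "coding_scheme": lib.coding.scheme if lib.coding else None,
            "dts": [t.dt for t in lib.trajectories],
        }
        if lib.coding is not None:
            arrays["codes"] = lib.coding.codes
        for k, t in enumerate(lib.trajectories):
            arrays[f"traj_{k}"] = t.values
        header["n_states"] = est.n_states_
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _rebuild_weights(z, header) -> ReservoirWeights:
    params = ReservoirParams(**header["reservoir_params"])
    n = params.N
    A = sp.csr_matrix((z["A_data"], z["A_indices"], z["A_indptr"]), shape=(n, n))
    W_out = z["W_out"]
    return ReservoirWeights(
        W_in=z["W_in"],
        W_index=z["W_index"],
        A=A,
        bias=z["bias"],
        params=params,
        W_out=W_out if W_out.size else None,
        guard_bound=float(header["guard_bound"]),
    )


def load_model(path: str | Path, expect: str | None = None):
    """Load a model saved by :func:`save_model`.

    ``expect`` ('memory' or 'classifier') makes loading the wrong kind a
    typed error instead of a surprise downstream.
    """
    from .classify import ReservoirClassifier

    with np.load(path, allow_pickle=False) as z:
        try:
            header = json.loads(bytes(z["header"]).decode())
        except Exception as exc:  # pragma: no cover
            raise ModelFormatError(f"not an rcmem model container: {path}") from exc
        kind = header.get("kind")
        if expect is not None and kind != expect:
            raise ModelFormatError(f"expected a {expect} model, found {kind!r}")
        weights = _rebuild_weights(z, header)
        if kind == "memory":
            est = ReservoirMemory(**header["init_params"])
            libmeta = header["library"]
            trajs = [
                Trajectory(z[f"traj_{k}"], dt=libmeta["dts"][k], name=name)
                for k, name in enumerate(libmeta["names"])
            ]
            coding = None
            if libmeta["coding_scheme"] is not None:
                coding = IndexCoding(
                    scheme=libmeta["coding_scheme"], K=len(trajs), codes=z["codes"]
                )
            est.library_ = AttractorLibrary(trajectories=trajs, coding=coding, names=libmeta["names"])
            est.weights_ = weights
            est.n_states_ = header["n_states"]
            est.n_dims_ = trajs[0].n_dims
        elif kind == "classifier":
            est = ReservoirClassifier(**header["init_params"])
            est.weights_ = weights
            est.classes_ = np.asarray(header["classes"])
        else:
            raise ModelFormatError(f"unknown model kind {kind!r}")
    return est


# ---------------------------------------------------------------------------
# Standard libraries ("the memories")

#: Vector-field time rescaling bringing each system to roughly 40-60 sampled
#: steps per oscillation cycle at dt = 0.1, so one reservoir (one leak rate)
#: can host them all.
_SIX_TIME_SCALES = {
    "lorenz": 0.25,
    "rossler": 1.0,
    "foodchain": 8.0,
    "hindmarsh_rose": 8.0,
}


def six_attractor_library(
    seed: int = 0,
    n_steps: int = 8000,
    coding: str | None = "scalar",
) -> AttractorLibrary:
    """The six-attractor reference library: a Lissajous curve, a periodic
    Sprott-F orbit, and the chaotic Lorenz, Rössler, food-chain and
    Hindmarsh–Rose attractors — all three-dimensional, z-normalized,
    sampled at dt = 0.1 after per-system time rescaling."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    def spec(name, **kw):
        return SystemSpec(
            name,
            integrate_dt=0.01,
            sample_every=10,
            transient_steps=2000,
            time_scale=_SIX_TIME_SCALES.get(name, 1.0),
            **kw,
        )

    trajs = [
        lissajous(n_steps, period_steps=40.0),
        integrate_system(spec("sprott_f", params={"a": 0.25}), n_steps, seed=int(seeds[1])),
        integrate_system(spec("lorenz"), n_steps, seed=int(seeds[2])),
        integrate_system(spec("rossler"), n_steps, seed=int(seeds[3])),
        integrate_system(spec("foodchain"), n_steps, seed=int(seeds[4])),
        integrate_system(spec("hindmarsh_rose"), n_steps, seed=int(seeds[5])),
    ]
    names = ["lissajous", "sprott_f_periodic", "lorenz", "rossler", "foodchain", "hindmarsh_rose"]
    normed = [normalize(t) for t in trajs]
    lib = AttractorLibrary(
        trajectories=normed,
        coding=make_coding(coding, 6) if coding else None,
        names=names,
    )
    return lib


#: The sixteen Sprott flows used for two-dimensional index coding: all the
#: canonical quadratic flows except A (conservative, no attractor) and the
#: two that are only marginally chaotic at this sampling (I, O).
_SPROTT16 = "bcdefghjklmnpqrs"


def sprott16_library(seed: int = 0, n_steps: int = 8000, coding: str = "kd_integer") -> AttractorLibrary:
    """Sixteen chaotic Sprott attractors at dt = 0.1, z-normalized, with a
    two-dimensional integer index code (levels 1..4 per channel)."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(_SPROTT16))
    trajs = []
    for letter, s in zip(_SPROTT16, seeds):
        spec = SystemSpec(
            f"sprott_{letter}", integrate_dt=0.01, sample_every=10, transient_steps=2000
        )
        trajs.append(normalize(integrate_system(spec, n_steps, seed=int(s))))
    return AttractorLibrary(
        trajectories=trajs,
        coding=make_coding(coding, 16, d=2),
        names=[f"sprott_{c}" for c in _SPROTT16],
    )


def dataset1_library(
    K: int,
    seed: int = 0,
    dims: int = 3,
    n_steps: int = 1600,
    coding: str = "one_hot",
) -> AttractorLibrary:
    """K independent random smooth periodic curves (period 200 steps), the
    workhorse dataset of the capacity-scaling experiments."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=K)
    trajs = [
        normalize(fourier_attractor(int(s), dims=dims, n_steps=n_steps)) for s in seeds
    ]
    return AttractorLibrary(
        trajectories=trajs, coding=make_coding(coding, K), names=[f"curve_{i}" for i in range(K)]
    )


_FIXTURES = {
    "six_attractors": lambda seed: six_attractor_library(seed=seed),
    "sprott16": lambda seed: sprott16_library(seed=seed),
    "dataset1_small": lambda seed: dataset1_library(8, seed=seed),
    "bifurcation100": lambda seed: bifurcation_library(100, seed=seed),
}


def make_fixture(name: str, seed: int = 0) -> AttractorLibrary:
    """Generate one of the named standard libraries."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}")
    return _FIXTURES[name](seed)
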