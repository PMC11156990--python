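"""Index codes and attractor libraries.

An :class:`AttractorLibrary` is an ordered collection of normalized target
trajectories together with one index code per attractor. The code is the
"address" of a stored pattern in a location-addressable reservoir memory:
it enters the network as a constant vector through a random projection,
effectively a per-neuron bias that selects which attractor the closed-loop
dynamics produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import Trajectory, normalize

__all__ = ["IndexCoding", "AttractorLibrary", "make_coding"]


@dataclass
class IndexCoding:
    """K index codes, one real vector of length ``n_channels`` per state."""

    scheme: str
    K: int
    codes: np.ndarray  # (K, n_channels)

    def __post_init__(self) -> None:
        self.codes = np.atleast_2d(np.asarray(self.codes, dtype=float))
        if self.codes.shape[0] != self.K:
            raise ValueError("need exactly one code per stored state")
        if self.K > 1:
            diffs = self.codes[:, None, :] - self.codes[None, :, :]
            dist = np.linalg.norm(diffs, axis=-1)
            np.fill_diagonal(dist, np.inf)
            if dist.min() == 0:
                raise ValueError("index codes must be pairwise distinct")

    @property
    def n_channels(self) -> int:
        return self.codes.shape[1]

    def code(self, i: int) -> np.ndarray:
        """Code vector for 1-based state index ``i``."""
        if not 1 <= i <= self.K:
            raise ValueError(f"state index {i} out of range 1..{self.K}")
        return self.codes[i - 1]


def make_coding(scheme: str, K: int, d: int = 2) -> IndexCoding:
    """Build one of the four index-assignment schemes.

    - ``scalar``: p_i = i (a single channel).
    - ``kd_integer``: d channels with integer levels 1..L, L = ceil(K**(1/d)).
    - ``binary``: ceil(log2 K) channels with levels in {-1, +1}.
    - ``one_hot``: K channels; code matrix is the identity.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if scheme == "scalar":
        codes = np.arange(1, K + 1, dtype=float)[:, None]
    elif scheme == "kd_integer":
        L = int(math.ceil(K ** (1.0 / d)))
        while L**d < K:  # guard against floating-point roundoff in the root
            L += 1
        grid = np.stack(
            np.meshgrid(*[np.arange(1, L + 1)] * d, indexing="ij"), axis=-1
        ).reshape(-1, d)
        codes = grid[:K].astype(float)
    elif scheme == "binary":
        n_bits = max(1, int(math.ceil(math.log2(K)))) if K > 1 else 1
        codes = np.empty((K, n_bits))
        for i in range(K):
            bits = [(i >> b) & 1 for b in range(n_bits)]
            codes[i] = [1.0 if b else -1.0 for b in bits]
    elif scheme == "one_hot":
        codes = np.eye(K)
    else:
        raise ValueError(f"unknown coding scheme {scheme!r}")
    return IndexCoding(scheme=scheme, K=K, codes=codes)


@dataclass
class AttractorLibrary:
    """Ordered collection of K normalized target trajectories plus codes."""

    trajectories: list[Trajectory]
    coding: IndexCoding | None = None
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ValueError("library must contain at least one trajectory")
        dims = {t.n_dims for t in self.trajectories}
        if len(dims) != 1:
            raise ValueError(f"all trajectories must share a dimension, got {dims}")
        if self.coding is not None and self.coding.K != len(self.trajectories):
            raise ValueError("coding size does not match the number of trajectories")
        if not self.names:
            self.names = [t.name or f"state_{i+1}" for i, t in enumerate(self.trajectories)]

    @property
    def K(self) -> int:
        return len(self.trajectories)

    @property
    def n_dims(self) -> int:
        return self.trajectories[0].n_dims

    def with_coding(self, scheme: str, d: int = 2) -> "AttractorLibrary":
        return AttractorLibrary(
            trajectories=self.trajectories,
            coding=make_coding(scheme, self.K, d=d),
            names=self.names,
        )

    @classmethod
    def from_trajectories(
        cls, trajectories: list[Trajectory], scheme: str | None = "scalar", d: int = 2
    ) -> "AttractorLibrary":
        """Normalize raw trajectories and attach a coding (or None)."""
        normed = [
            t if abs(t.values.mean()) < 1e-9 and abs(t.values.std() - 1) < 1e-6 else normalize(t)
            for t in trajectories
        ]
        coding = make_coding(scheme, len(normed), d=d) if scheme else None
        return cls(trajectories=normed, coding=coding)
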