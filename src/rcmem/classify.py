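"""Reservoir classifier for short output segments.

A second, independent reservoir is trained to label a short time-series
segment as one of the K stored states or as "none" (label 0) — static
outputs, drifts, noise, or any other untrained behavior. It is the
measurement device of the whole package: transition matrices, failed-switch
detection, cue-recall success rates and the feedback-control loop all rely
on its verdicts.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .coding import AttractorLibrary
from .dynamics import Trajectory
from .reservoir import (
    ReservoirParams,
    RidgeAccumulator,
    drive,
    init_reservoir,
    make_features,
)

__all__ = ["ReservoirClassifier", "train_classifier", "synthesize_negatives"]

NONE_LABEL = 0


def synthesize_negatives(
    n_dims: int,
    seed: int = 0,
    n_each: int = 6,
    segment_len: int = 400,
) -> list[np.ndarray]:
    """Non-target segments for the "none" class: constants at random levels,
    large-amplitude linear drifts, and white noise at several scales.

    Constant (static) outputs are the most common failure mode of a memory
    reservoir, and the driven classifier state depends strongly on the
    level, so the constants are sampled much more densely than the other
    negative families.
    """
    rng = np.random.default_rng(seed)
    segs: list[np.ndarray] = []
    for _ in range(8 * n_each):
        level = rng.uniform(-3, 3, size=n_dims)
        segs.append(np.tile(level, (segment_len, 1)))
    for _ in range(n_each):
        a = rng.uniform(-5, 5, size=n_dims)
        b = rng.uniform(-5, 5, size=n_dims)
        t = np.linspace(0, 1, segment_len)[:, None]
        segs.append(a + (b - a) * t)
    for sigma in (0.5, 1.0, 3.0):
        for _ in range(max(1, n_each // 3)):
            segs.append(sigma * rng.standard_normal((segment_len, n_dims)))
    return segs


class ReservoirClassifier(BaseEstimator, ClassifierMixin):
    """K+1-way reservoir classifier over sliding time-series windows.

    ``fit`` drives the (fixed, random) reservoir over labeled segments and
    ridge-regresses per-step one-hot label targets; ``predict`` aggregates
    the per-step scores over the last ``window_steps`` of a segment and
    takes the argmax (ties resolve to "none", label 0).
    """

    def __init__(
        self,
        N: int = 500,
        spectral_radius: float = 0.9,
        density: float = 0.02,
        input_scale: float = 1.0,
        bias_scale: float = 0.2,
        leak: float = 0.5,
        ridge_beta: float = 1e-4,
        readout_features: str = "linear_plus_square",
        washout: int = 50,
        window_steps: int = 100,
        train_noise: float = 0.05,
        min_score: float = 0.8,
        seed: int = 0,
    ):
        self.N = N
        self.spectral_radius = spectral_radius
        self.density = density
        self.input_scale = input_scale
        self.bias_scale = bias_scale
        self.leak = leak
        self.ridge_beta = ridge_beta
        self.readout_features = readout_features
        self.washout = washout
        self.window_steps = window_steps
        self.train_noise = train_noise
        self.min_score = min_score
        self.seed = seed

    def _make_params(self, n_dims: int) -> ReservoirParams:
        return ReservoirParams(
            N=self.N,
            D_in=n_dims,
            C_index=0,
            spectral_radius=self.spectral_radius,
            density=self.density,
            input_scale=self.input_scale,
            index_scale=0.0,
            bias_scale=self.bias_scale,
            leak=self.leak,
            ridge_beta=self.ridge_beta,
            readout_features=self.readout_features,
            washout=self.washout,
            seed=self.seed,
        )

    def fit(self, X: list, y: list | np.ndarray) -> "ReservoirClassifier":
        """Train from labeled segments.

        ``X``: list of (T_i, D) arrays or Trajectories; ``y``: integer labels,
        0 reserved for "none".
        """
        segs = [x.values if isinstance(x, Trajectory) else np.asarray(x, float) for x in X]
        y = np.asarray(y, dtype=int)
        if len(segs) != len(y):
            raise ValueError("X and y length mismatch")
        n_dims = segs[0].shape[1]
        self.classes_ = np.unique(np.concatenate([[NONE_LABEL], y]))
        n_classes = int(self.classes_.max()) + 1
        params = self._make_params(n_dims)
        rc = init_reservoir(params)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xC1A55]))
        acc = RidgeAccumulator(params.n_features, n_classes)
        for seg, label in zip(segs, y):
            u = seg
            if self.train_noise > 0:
                u = u + self.train_noise * rng.standard_normal(u.shape)
            states = drive(rc, u)
            feats = make_features(states[self.washout :], self.readout_features)
            onehot = np.zeros((len(feats), n_classes))
            onehot[:, label] = 1.0
            acc.add(feats, onehot)
        rc.W_out = acc.solve(self.ridge_beta)
        rc.guard_bound = np.inf
        self.weights_ = rc
        self.n_dims_ = n_dims
        return self

    # -- inference ----------------------------------------------------------

    def decision_scores(self, segment: Trajectory | np.ndarray) -> np.ndarray:
        """Mean per-class score over the last ``window_steps`` driven states."""
        if not hasattr(self, "weights_"):
            raise ValueError("classifier is not fitted")
        u = segment.values if isinstance(segment, Trajectory) else np.asarray(segment, float)
        if len(u) < self.window_steps:
            raise ValueError(
                f"segment has {len(u)} steps; needs at least window_steps={self.window_steps}"
            )
        states = drive(self.weights_, u)
        feats = make_features(states[-self.window_steps :], self.readout_features)
        return np.mean(feats @ self.weights_.W_out.T, axis=0)

    def classify(self, segment) -> tuple[int, np.ndarray]:
        """Label a segment.

        The winning class must beat the one-hot training level by a clear
        margin (score >= ``min_score``); hesitant verdicts and exact ties
        resolve to "none", which conservatively favors triggering control.
        """
        scores = self.decision_scores(segment)
        best = int(np.argmax(scores))
        if np.sum(scores == scores[best]) > 1 or scores[best] < self.min_score:
            return NONE_LABEL, scores
        return best, scores

    def predict(self, X: list) -> np.ndarray:
        return np.asarray([self.classify(x)[0] for x in X], dtype=int)

    def score_windows(self, segment, stride: int = 25) -> list[tuple[int, int]]:
        """Sliding-window labels over a long segment: list of (start, label)."""
        u = segment.values if isinstance(segment, Trajectory) else np.asarray(segment, float)
        states = drive(self.weights_, u)
        feats = make_features(states, self.readout_features)
        scores = feats @ self.weights_.W_out.T
        out = []
        w = self.window_steps
        for start in range(self.washout, len(u) - w + 1, stride):
            s = scores[start : start + w].mean(axis=0)
            best = int(np.argmax(s))
            out.append((start, best))
        return out


def train_classifier(
    library: AttractorLibrary,
    negatives: list | None = None,
    train_steps: int = 2000,
    n_segments_per_state: int = 3,
    seed: int = 0,
    **kw,
) -> ReservoirClassifier:
    """Fit a classifier on a library: positive segments cut from each stored
    attractor's reference series plus a synthesized (or supplied) pool of
    non-target segments for the "none" class."""
    clf = ReservoirClassifier(seed=seed, **kw)
    X: list[np.ndarray] = []
    y: list[int] = []
    for i, traj in enumerate(library.trajectories, start=1):
        u = traj.values
        seg_len = min(train_steps, (len(u) - 1) // n_segments_per_state)
        for k in range(n_segments_per_state):
            X.append(u[k * seg_len : (k + 1) * seg_len])
            y.append(i)
    if negatives is None:
        negatives = synthesize_negatives(library.n_dims, seed=seed + 1)
    for seg in negatives:
        X.append(seg.values if isinstance(seg, Trajectory) else seg)
        y.append(NONE_LABEL)
    return clf.fit(X, y)
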