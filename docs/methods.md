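# Methods

## The reservoir model

All memories live in a leaky-tanh echo state network with hidden state
`r ∈ R^N`:

    r(t+1) = (1 − α) r(t) + α tanh(A r(t) + W_in u(t) + W_index p + b)
    v(t)   = W_out φ(r(t)),     φ(r) = [r; r²]  (default)

`A` is sparse Erdős–Rényi (density 0.02, but never below an average
in-degree of 10 so small reservoirs are not nilpotent) with uniform[−1, 1]
weights rescaled to spectral radius ρ; `W_in`, `W_index` and the bias `b`
are dense uniform with scales listed below. Only `W_out` is trained. The
quadratic feature map breaks the odd symmetry of tanh — with a purely
linear readout, every stored attractor would coexist with its mirror image.

**Training (batch).** For each stored attractor the reservoir is driven
open-loop by the attractor's (z-normalized) time series together with that
attractor's index code; after a washout the driven features are pooled over
all K attractors and a single ridge regression maps `φ(r(t))` to the next
input sample `u(t+1)`. The normal equations are accumulated per segment
(symmetric rank-k updates), so the full design matrix is never formed.
Every attractor contributes the same number of regression samples so no
state dominates the fit.

**Noise injection.** During the training drive, Gaussian noise of standard
deviation `train_noise` is added to the *input* while the regression
targets stay clean. This is the decisive stabilizer of the whole
construction: it teaches the readout to contract a finite tube around each
target orbit back onto the orbit. Without it the one-step fit is nearly
perfect (training RMSE ~1e−3) yet every closed-loop recall from a random
initial hidden state runs away to spurious fixed points — the stored
orbits exist but are not attracting and have no usable basins. With it, the
six-attractor reference task recalls every state from random initial
conditions with ~90% success per trial.

**Closed loop and the divergence guard.** After training the output is fed
back as input. Outputs are clipped at `guard_factor` (10×) the maximum
absolute training value; any clipping sets a `diverged` flag. The clip is a
saturation, not an abort: the hidden state is bounded by tanh, so a
transient excursion can still fall back onto a stored attractor (cold-start
recall depends on this), while a run that stays pinned at the clip rail is
a genuinely failed recall that the classifier labels "none".

## Default hyperparameters

| parameter | default | meaning / rationale |
|---|---|---|
| `N` | 1000 | reservoir size of the six-attractor reference tasks |
| `spectral_radius` | 0.9 | standard near-critical echo-state regime |
| `density` | 0.02 | sparse recurrent connectivity |
| `input_scale` | 1.0 | strong input coupling; at 0.3 the index basins collapse (see above) |
| `index_scale` | 0.3 | scalar codes p=1..6 then span biases up to ±1.8, inside the useful tanh range |
| `bias_scale` | 0.2 | mild static heterogeneity of the neurons |
| `leak` | 0.5 | matches targets with 40–60 samples per oscillation cycle |
| `ridge_beta` | 1e−6 | regularization; training is noise-regularized already |
| `train_noise` | 0.03 | input-noise std during training (z-scored units) |
| `washout` | 200 steps | discarded transient per training segment |
| `train_steps` | 5000 | regression samples per attractor |
| `guard_factor` | 10 | output clip at 10× the training amplitude |

All randomness is owned by explicit integer seeds; weight initialization,
training noise, recall initial states and every experiment are bit-for-bit
reproducible, and serialized models (npz container: weight arrays plus a
JSON header) round-trip exactly.

The classifier reservoir (N=500, same update rule, no index channel) maps
driven states to K+1 one-hot label targets; a segment's label is the argmax
of the mean score over the last 100 driven steps, demoted to "none" when
the winning score falls below 0.8 — positives score ≈1.0, so the margin
rejects hesitant verdicts, which conservatively favors triggering control.
Its "none" class is trained on synthesized negatives: constants at random
levels (sampled densely — static outputs are the dominant failure mode and
the driven state depends strongly on the level), linear drifts, and white
noise at several amplitudes.

## Target states

Targets are generated by fixed-step RK4 (default dt=0.01, sampled every 10
steps → Δt=0.1) from canonical parameter sets: Lorenz (10, 28, 8/3),
Rössler (0.2, 0.2, 5.7), Hindmarsh–Rose in the chaotic bursting regime
(I=3.25, r=0.006), a resource–consumer–predator food chain with Holling
type-II interactions (x_c=0.4, y_c=2.009, x_p=0.08, y_p=2.876, R0=0.16129,
C0=0.5, carrying capacity K_f as the bifurcation parameter), and the
canonical quadratic (Sprott) flows. Every stored series is z-normalized per
dimension (population std), with the affine transform retained for inverse
mapping.

A single leak rate serves all six reference attractors because the vector
fields are time-rescaled before integration (Lorenz ×0.25, food chain ×8,
Hindmarsh–Rose ×8) so each system completes an oscillation cycle in 40–60
sampled steps at Δt=0.1. The "periodic Sprott" member of the six-attractor
library is the Sprott F flow with its damping coefficient lowered to
a=0.25, where the canonical chaotic attractor gives way to a stable limit
cycle. The 16-flow library uses all canonical quadratic flows except A
(conservative — no attractor) and I, O (only marginally chaotic at this
sampling).

**Random smooth curves (capacity dataset).** Each dimension independently:
2–5 control points at uniform random phases within one 200-step period,
ordinates uniform in [−1, 1], interpolated by the minimum-norm least-squares
fourth-order Fourier series. The curves are exactly periodic at integer
steps and arbitrarily numerous — the workhorse of the scaling experiments.
A two-dimensional variant with a 36-step period serves as a fully synthetic
stand-in for a rotating-objects video task (two leading principal
components of a looping video); no real video data is involved.

**Bifurcation sweep.** 100 food-chain states at evenly spaced K_f in
[0.92, 1], sampled at Δt=1, with scalar index values evenly spaced on
[−2.5, 2.5] ordered by K_f. Near the top of the interval the chaotic set
loses stability through a boundary crisis and the predator can go extinct
(the state collapses to a two-species cycle); collapsed states are retried
from fresh initial conditions with a short transient, which samples the
long chaotic transient instead of the dead equilibrium.

## Retrieval protocols

- **Indexed recall**: hidden state drawn uniform(−0.5, 0.5)^N (seeded),
  1000–2000 settling steps of closed-loop operation under the target code,
  then generation. Failure (≈10% of cold starts, concentrated on the
  bursting neuron state) parks the loop on an untrained state.
- **Switching**: the index changes while the hidden state and last output
  are inherited; 100 settling steps, then a 200-step window is classified.
  Switch trials start from snapshots of the source attractor taken at
  random times of a closed-loop run.
- **Index-free cue recall**: random hidden state, open-loop warm-up over a
  cue segment cut from the target's reference series at a random phase,
  then 250 closed-loop steps; success = classifier label equals the cued
  state. Partial cues drive the present input channels from the cue while
  the missing channels are rewired to the model's own output during
  warm-up; noisy cues add i.i.d. Gaussian noise to the cue.
- **Basin probes**: on-attractor hidden states are perturbed along random
  orthonormal directions (2-D ε-grids for basin slices, random kicks of
  fixed magnitude for robustness curves) and the reached attractor is
  classified. The matching output accompanies the perturbed hidden state so
  the probe measures the basin, not an input discontinuity.
- **Distance to the embedding**: nearest-neighbor Euclidean distance from
  the warming hidden state to a 1000-state reference cloud collected while
  driving on the target. The ensemble mean decays exponentially with cue
  length until it reaches the cloud's sampling-density floor; fits of the
  decay exclude the floor (range: mean distance > 2× its final plateau).

## Control strategies

- **Tactical detour**: exhaustive search over simple index paths (K is
  small) maximizing the product of per-hop transition rates. When
  correcting a *known-failed* switch the direct path is excluded from the
  search — repeating the identical switch from the same state is
  deterministic and fails again.
- **Feedback control**: classify; if wrong, inject `T_n` steps of Gaussian
  noise and retry, up to `max_cycles`. The noise *replaces* the input
  during the perturbation: failed switches often park the loop on a
  strongly attracting untrained state whose output is pinned at the clip
  rail, where merely adding noise to the fed-back output is negligible.
  Expected reach time is (T_n + T_c)/η_ij.
- **Cue warm-up**: set the target's index, drive with a short segment of
  the target's own series, release. A couple of dozen cue steps corrects
  essentially all harvested failures.

## Recall measures

- **Largest Lyapunov exponent** (nearest-neighbor divergence): for ~4000
  reference points, the nearest neighbor outside a Theiler window (one
  average period) is tracked and the mean log separation is fitted where it
  has grown 0.5–2 nats above the initial separation and is at least 1.5
  nats below the random-pair saturation level — after the neighbor-alignment
  transient and before the saturation bend. Scalar series are delay-embedded.
  The window rule was calibrated on the analytic logistic-map value (ln 2)
  and the literature Lorenz exponent.
- **Correlation dimension** (Grassberger–Procaccia): pair-correlation sums
  on a random subsample (default 15k points) over 32 log-spaced radii;
  slope fitted over the central 50% of the log-radius interval where pair
  counts ≥ 200 and C(r) ≤ 0.1 (below the attractor-size saturation).
  Calibrated on a circle (d=1), a uniform square (d=2) and the literature
  Lorenz value 2.05.
- **Short-term measures**: prediction horizon = first time any dimension's
  deviation exceeds 10% of that dimension's oscillation amplitude (half of
  max − min of a long reference), in units of the (average) period, minimum
  over dimensions; RMSE over a four-period window; region-escape time =
  first exit from the reference bounding box widened by 10% of its extent
  (5% per side). Success thresholds are fixed within a task: horizon ≥ 2
  periods, RMSE ≤ 0.3 (z-scored units), ≥ 4 periods inside the box.

## Capacity scaling

For each (K, N): an ensemble of reservoirs is trained on K freshly drawn
states; each stored state is warm-started on 100 reference steps and its
closed-loop continuation is scored by all three measures against the true
continuation; a network succeeds when *every* stored state passes (the
all-pass convention; an average criterion would blur the transition). The
success-vs-N curve is sigmoid-like; N_c is the grid point closest to the
50% crossing, restricted to the two points bracketing the crossing so that
a transition steeper than the grid cannot alias to a distant tied point;
γ is the slope of log N_c vs log K.

The smooth-curve dataset (200-step periods — slow relative to the
reference attractors) uses a per-task configuration fixed after pilot runs:
leak 0.2, train_noise 0.003, washout 100, 800 training steps per state.
Default grids are geometric and proportional to K. At desk scale (K ≤ 32,
ensembles of 5–6) the one-hot exponent lands close to the linear law
(γ ≈ 1.0–1.08); one-hot and binary coding are indistinguishable within
grid resolution (their exponents are equal; the one-hot advantage is a
prefactor that emerges at larger K), while 2-D integer coding needs a
clearly larger reservoir at matched K.

## What the synthetic generators do and do not emulate

The generators reproduce the structural properties that the method
exercises: deterministic low-dimensional flows with distinct climates,
arbitrarily many mutually independent smooth periodic curves, a
parameter-continuum of correlated states (the bifurcation sweep), and a
low-dimensional periodic stand-in for video loops. They do not emulate
measurement noise on the stored series, non-stationary or input-driven
systems, high-dimensional targets, or real video statistics (the stand-in
shares only dimensionality and periodicity with a PCA-reduced video).
Passing tests therefore demonstrate the storage/retrieval machinery on
clean low-dimensional dynamics, not performance on noisy or
high-dimensional real-world recordings.

## Numerical choices and limitations

- Fixed-step RK4 throughout; convergence checked by step-halving on
  periodic orbits (< 1e−5 per step over ten cycles). No stiff-ODE support.
- Spectral radii via Arnoldi iteration with a fixed start vector (dense
  eigensolve for N ≤ 400 and as fallback), exact to 1e−6 after rescaling.
- The ridge Gram matrix is accumulated in float64 via symmetric rank-k
  updates; permuting the stored states changes the summation order and
  hence the readout only at the 1e−7 level.
- Switching in this configuration fails at ~3–8% depending on the network
  realization — somewhat more reliable than the ~9% of the reference
  setting; failure rates are strongly destination-dependent, and vary
  widely between random reservoir realizations.
- The bursting (Hindmarsh–Rose) state is the hardest to recall from cold
  starts and dominates the failure statistics; slow–fast targets stretch
  the single-leak-rate assumption.
- Sequential (one-attractor-at-a-time) learning is out of scope: training
  is a single pooled regression, so adding a state means retraining.
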