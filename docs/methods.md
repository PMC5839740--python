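# Methods

## Model and assumptions

The package implements a one-dimensional, linear-Gaussian state-space model
of self-motion and estimates it with a constant-gain (steady-state) Kalman
filter. The generative model is

    X(t) = D X(t−1) + M Xu(t) + E Xε(t),   Xε ~ N(0, Q)
    S(t) = T X(t) + Sη(t),                 Sη ~ N(0, R)

where `Xu` are motor commands known to the estimator and `Xε` are
unpredicted perturbations — passive motion imposed from outside or motor
error. The estimator is assumed to know `D, M, E, T, Q, R` exactly (a
correct internal model), except in the deliberate ablation variant below.

Motion is restricted to one rotation axis (e.g. roll) and one translation
axis (inter-aural). Tilt and small linear accelerations are expressed in
the same g-equivalent units (a small acceleration `A` perpendicular to
gravity deflects the gravito-inertial vector by `≈ A` rad), which is what
lets the otolith ambiguity be written as a plain sum `F = G + A`.

### State variables and sensors

Head-only model (`make_rotation_tilt_model`, states `Ω, C, G, A`):

- `Ω` and `A` have no persistence: each step they equal command +
  perturbation. There is no memory in the stimulus itself; all dynamics
  live in the hidden states. The zero-mean priors on `Ωε` and `Aε` are what
  pull passive estimates back to zero over time.
- `C`, the canal state, relaxes as `C(t) = (1 − δt/τc) C(t−1) + (δt/τc) Ω(t)`;
  the canals report `V = Ω − C`, a first-order high-pass of velocity with
  time constant `τc`. During sustained rotation `V` decays with `τc` and
  shows the classic negative aftereffect at the stop.
- `G`, tilt, integrates `δt·Ω(t)` when rotation is about an earth-horizontal
  axis (`gravity_coupled=True`) and is frozen for earth-vertical-axis
  rotation (EVAR). The otoliths report `F = G + A` and cannot separate the
  two by themselves.

Head–neck model (`make_neck_model`, states `ΩTS, ΩHT, N, C`): trunk-in-space
and head-on-trunk velocities are perturbed independently (`σTS = 0.7`,
`σHT = 3.5 rad/s` — head-on-trunk movement is far more variable), neck
position `N` integrates `ΩHT`, the canal state integrates total head
velocity, and the sensors are `V = ΩTS + ΩHT − C` and position-coding
proprioceptors `P = N`.

### Discretisation

Within a step, the freshly drawn velocity (command + perturbation) feeds
the `C`, `G` and `N` integrators at the same step: the couplings are
carried in the `M` and `E` columns, not in `D`. This keeps `G = ∫Ω dt`
lag-free and reproduces the reference gain tables at `δt = 0.01 s`. A
consequence worth knowing: in the *filter*, the integrators advance only
through commands and feedback — the tilt estimate during passive motion is
literally the accumulated tilt feedback, `Ĝ = ∫Gk`.

## Steady-state gain

`steady_state_gain` iterates the standard covariance recursion
(prior ← `D P D' + E Q E'`; gain ← `prior T' (T prior T' + R)⁻¹`;
posterior ← `(I − K T) prior`) from zero posterior covariance until the
max-abs change in `K` is below `1e-12` (cap `1e6` iterations; these models
converge in 3k–15k). The innovation covariance is handled by a linear
solve, never an explicit inverse: with `σV = 0.175 rad/s` against
`σF = 0.002 g` the system is poorly scaled. The posterior is re-symmetrised
each step. Initialisation does not matter at the reported precision: the
fixed point is unique for these observable, noise-driven models, and the
suite cross-checks the converged gain against an independently coded
time-varying filter (Joseph-form update, explicit inverse). The
head-only models settle within `1e-8` of the 10⁴-step time-varying gain;
the head–neck recursion converges more slowly (the proprioceptive noise is
tiny), so its cross-check runs the time-varying filter to 4×10⁴ steps.

The filter then uses this single constant `K` at every step; the
time-varying filter exists only as a test oracle.

### Gain-table classification

`gain_table` recomputes `K` at `δt ∈ {0.005, 0.01, 0.02}` (holding
continuous-time parameters fixed) and assigns each entry the `δt`-power
normalisation (`1`, `δt`, or `1/δt`) whose coefficient varies least across
the sweep, with a `stable` flag when that variation is within 5%. The
head-only coefficients are cleanly `δt`-stable; the head–neck ones are only
approximately so (e.g. the canal-to-trunk gain moves 0.67 → 0.85 → 0.92
across the sweep), so the class label there reflects the best fit at the
reference step, not an exact power law. An entry is flagged *negligible*
when its influence is ≤ 0.05 — the raw gain for memoryless states (a
`δt`-sized kick that never accumulates), the normalised coefficient for
integrator states (where per-step kicks compound).

Computed coefficients agree with the reference values at two decimals for
most entries; a handful sit one unit of the second decimal away
(canal-to-tilt 0.91·δt, proprioceptive-to-trunk −0.85/δt, neck-position
0.95), and the head–neck canal-to-`C` entry computes to 0.19·δt. Probing
alternative discretisations (lagged coupling, trapezoidal integration,
exponential decay factors, `σF` sweeps) and finite-horizon gain recursions
moves none of these toward consistent agreement, so the converged values
are reported as-is. Where the literature itself prints two values for the
same entry (otolith-to-acceleration 0.99 vs 0.995; otolith-to-tilt 0.76·δt
vs 0.5·δt), this implementation computes 0.992 and 0.757·δt, matching the
tabulated values.

## Protocols

Stimuli default to unit peak amplitude (1 rad/s or 1 g); the model is
linear, so every claim here is scale-invariant. Trapezoidal velocity
profiles carry ramps of one-tenth the stimulus duration per side; Gaussian
profiles (for the active component of superposition paradigms) use
SD = duration/6 and have numerically negligible (< 1e-4) tails at the
record edges; long-duration stimuli are plain steps that do not return to
zero. Short stimuli sit inside a longer quiet record so aftereffects are
visible. These shapes are conventions — they do not affect gains or any
zero-error identity. Every preset exists in `_active` (command-channel) and
`_passive` (perturbation-channel) variants that generate bit-identical true
motion.

`random_protocol` draws per-step white Gaussian perturbations from the
model's own priors — deliberately matched to the generative assumptions, so
it probes internal consistency (e.g. estimator unbiasedness), not
robustness to realistic motion statistics.

## Simulation conventions

Zero initial state and zero initial estimate; sensor noise off by default
(the noise-free run equals the mean over noisy runs, which the suite
verifies over 200 seeded repetitions), with a mandatory seed whenever noise
is drawn. Feedback is stored per (state, sensor) pair, `K[i,j]·δS[j]`, so
canal-driven and otolith-driven corrections remain separable; the identity
`X̂ = X̂p + Σ feedback` holds exactly, not to tolerance.

During active, unperturbed, noise-free motion the filter's prediction step
performs bit-for-bit the same arithmetic as the world update, so sensory
errors are exactly zero — the central active/passive dissociation is exact
in this implementation, not approximate.

### A quantitative caveat on passive tilt

Passive tilt leaves a small but nonzero otolith error: the tilt feedback
gain (0.91·δt) under-integrates the canal-derived tilt velocity by ~9%, and
that deficit appears transiently in `δF` until the otolith feedback loop
absorbs it. With a translation whose acceleration replays the identical
otolith profile, the tilt-condition error peaks at ~14% of the
translation-condition error — about an order of magnitude smaller, which is
the substance of the tilt/translation dissociation, but not below a strict
10% ratio.

## Alternative schemes and nonlinearities

- *Sensory suppression*: the filter with all gains zeroed; estimates follow
  commands only and passive motion goes completely undetected.
- *Parallel scheme*: a motor-only branch (commands through the true
  kinematics) and a sensory-only branch (the filter without commands),
  subtracted to give a motion prediction error, plus a `w_motor`-weighted
  merged estimate. Indistinguishable from the unified filter on brief
  passive rotations; during a 60-s active rotation its prediction error
  grows to ~97% of stimulus velocity while the unified filter's stays zero,
  and no weighting rescues the merged percept.
  The third conceivable variant — feeding sensory prediction errors into
  the sensory internal model — is mathematically a re-arrangement of the
  unified filter and is documented rather than implemented.
- *Proprioceptive-mismatch gate*: zeroes the motor-command input on every
  step where `|δP|` exceeds a threshold (default 0.01 rad, ~6 proprioceptive
  noise SDs, so sensor noise alone never trips it; the true value is not
  established). Single threshold, no hysteresis or refractory period.
- *Neck-offset noise modulation*: a static head-on-trunk offset multiplies
  `σP` by `1 + 2|offset|` (a 0.5 rad ≈ 29° offset doubles the noise). The
  mapping is a package convention; only its qualitative consequences are
  asserted — trunk-velocity ("bimodal") response gains fall identically for
  vestibular and proprioceptive stimulation while head-velocity
  ("unimodal") gains stay within 5%.

## Metrics

Decay time constants come from a least-squares line through `log(series)`
on a caller-chosen window (the series must be positive and decaying there).
Sinusoidal gain/phase projects response and stimulus onto sin/cos at the
stimulus frequency (≥ 3 cycles required; a constant regressor absorbs
offsets). The attenuation index is `1 − peak|active| / peak|passive|`.

## Problem sizes

Default runs use `δt = 0.01 s`: 100–600 steps for transient stimuli, 6000
for the 60-s velocity-storage and scheme-discrimination runs, 200
repetitions for the noise-averaging check. Everything completes in seconds
on one core.

## Limitations

One rotation + one translation axis; no 3-D kinematics or quaternion
states, no eye movements or reflex generation, no motor-plant model or
adaptation dynamics, no naturalistic motion statistics. Proprioceptors are
pure position sensors (real neck afferents carry velocity components at
high frequency; published checks indicate the conclusions survive that
change, but it is not modeled here). Passing tests demonstrate internal
consistency with the stated generative model, not fidelity to any
particular recorded dataset.
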