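# Methods

`navinfer` simulates a rodent-like agent in a 2D maze and carries out five
spatial-cognition computations — self-localisation, sensory imagery,
decision making, environment (model) selection and route/motor planning —
as forward and backward Gaussian inference in one nonlinear state-space
model. This note records the model, the parameter choices that matter, the
numerical conventions, and what the simulations do and do not establish.

## The generative model

**Hidden state.** `x_t = (x, y, v, θ)`: allocentric position (y-axis up),
speed and heading. Headings are measured *clockwise* from the positive x
axis, so the unit heading vector is `(cos θ, −sin θ)` and `θ = −π/2` points
north. Controls `u_t = (a, ω)` are a speed drive (units/s²) and a heading
drive (rad/s).

**Dynamics.** Continuous-time drift with linear friction,

    ẋ = v cos θ,  ẏ = −v sin θ,  v̇ = a − k v,  θ̇ = ω,

integrated over `dt` with a fixed-step 4th-order Runge–Kutta scheme, plus
additive Gaussian state noise `w_t ~ N(0, Q)`. Defaults: `k = 1`,
`dt = 0.01`, horizons of `n = 1000` steps. Flow matrices (the Jacobians of
the discrete one-step map) are available analytically (exact stage-wise
differentiation of the RK4 map), by central finite differences, or by a
local least-squares regression over perturbed one-step simulations; the
analytic route is what inference uses.

**Observations.** The environment is a unit-square arena with four
coloured boundary walls (0.14 north, 0.29 east, 0.43 south, 0.57 west),
two inner walls (0.71 west wall from (0.35, 0) to (0.35, 0.6); 0.86 east
wall from (0.65, 0.4) to (0.65, 1.0)) and one olfactory source at
(0.1, 0.1) whose signal is `s·exp(−d/λ)` with `s = 1`, `λ = 0.3` (an
isotropic diffusion kernel in the source distance `d`; the linear-distance
exponent is a declared choice, isolated in one function). The agent
senses: olfaction (scalar), touch (minimum Euclidean distance to any
wall), and a 1-D retina of `P = 20` pixels sampling wall colour by ray
casting over ±45° around the heading. Corner ties go to the nearest
intersection; endpoint grazes count as hits.

The agent's own observation model `g(x; M_i)` predicts these channels from
a basis expansion: olfaction and touch are linear read-outs of `B = 100`
place cells (isotropic Gaussian bumps on a 10×10 grid, width σ_b = grid
spacing = 0.1); each retinal pixel is a linear read-out of the 3200-cell
conjunctive product of the place basis with `J = 32` head-direction cells,
`h_j(ψ) = exp(β(cos(ψ − ψ_j) − 1))` with shared sharpness `β = 10`
(≈ ±25° at half height), the head-direction bank being evaluated at
`θ + α_p` for pixel offset `α_p`. An optional speed channel observes `v`
directly and exists only in planning mode.

**Weight learning.** Weights are fit by ridge least squares
(`ridge = 1e−6` for numerical stability) on noiseless exemplars with known
states: 15×15 uniformly spaced locations (225 exemplars) for olfaction and
touch, and the same 225 locations × 47 uniformly spaced headings (10,575
exemplars) for vision. Because every location is paired with every
heading, the conjunctive normal matrix factorises as a Kronecker product
`C_φ ⊗ C_h`, which we solve per pixel in the joint eigenbasis of the two
factors — training the full model takes well under a second. A generic
per-pixel solver handles arbitrary (non-grid) exemplar sets.

**Observation noise.** Block-diagonal `Φ` with `σ_o² = 0.01` (olfaction),
`σ_d² = 0.01` (touch), `Σ_v = 0.1·I_P` (vision) and `σ²_speed = 0.01`,
ordering the modalities so the agent trusts olfaction and touch most and
vision least. Tasks may override single blocks; localisation and decision
making raise `σ_d²` to `1e6`, effectively ignoring touch, because distance
to the nearest wall takes the same value at many distinct locations.

## Inference

Forward inference is an extended Kalman filter: the mean is propagated
through the exact nonlinear map while covariances use the flow matrices;
the correction is in Joseph-stabilised form with explicit symmetrisation
each step and all solves via Cholesky factorisation, with the innovation
covariance floored at `1e−10·I`. In the scalar linear case the corrected
mean is exactly the precision-weighted average of the path-integral and
sensory estimates (a tested invariant). The "lesioned" variant removes the
correction entirely (gain forced to zero), leaving pure probabilistic path
integration.

The sequence log-likelihood accumulates the Gaussian predictive densities
of the innovations. Its per-modality decomposition conditions the channels
sequentially in their stored order (olfaction, touch, vision, speed)
through the Cholesky factor of the innovation covariance; the terms sum to
the total exactly and reduce to the marginal densities when
cross-modality couplings vanish. The decomposition is order-dependent in
principle; with the default noise levels the couplings are small and the
ordering immaterial in practice.

Backward inference is the RTS-form gamma-recursion smoother, which refines
estimates retrospectively without storing observations; the equivalent
batch (joint-precision) smoother exists only in the test-suite as an
independent oracle.

Control inference (planning) augments the state with the control vector,
which evolves as a random walk with covariance `Q_u`, and reuses the same
forward/backward machinery; the planned motor sequence is the control
block of the smoothed augmented beliefs. A decoupled backward recursion
that ignores state–control cross-covariances is available as a cross-check
mode. Note an index convention: the smoothed control at step `t` is the
one driving the transition into step `t + 1`.

## Task constructions and the choices behind them

**Canonical trajectories.** The four compass trajectories (NE, NW, SE, SW)
start at the maze centre at rest: a sustained speed drive `a = 0.1` over
the first half of the steps then coast-to-rest under friction, and a
smooth raised-cosine heading pulse over steps 10–40% integrating to
0.8π·0.3 ≈ 43°. NE and NW start heading north and differ only in the sign
of the heading drive; SE and SW flip the initial heading. The amplitudes
are scaled so all four paths remain strictly inside the arena (a
front-loaded impulsive drive either exits the unit maze or degenerates
into a straight dash with a turn-in-place tail).

**Localisation.** Ground truth is the noiseless SE trajectory. Each trial
perturbs the filter's path-integration update with per-step position noise
(sd 0.01) and supplies observations drawn with the base sensory noise; the
same perturbations and observations feed the intact and lesioned filters,
so the ablation is paired. The error metric is the mean Euclidean distance
between true and estimated position over the trajectory, averaged over 50
trials; the headline number is the percent reduction
`100·(1 − intact/lesioned)`.

**Imagery.** Noiseless path integration generates predicted retinal
sequences, scored per retinal angle as the proportion of variance
explained, `R²_p = 1 − SSE_p/SST_p`. Pixels that stare at a single wall
colour for the whole trajectory have `SST_p = 0`, making `R²` degenerate;
such pixels are scored against the scene's mean per-pixel temporal
variance, and a fully constant scene against a nominal colour variance of
0.01 (about one wall-colour step squared). Central pixels (inner 20%) are
compared with peripheral ones (outer 20%).

**Decision making.** Two candidate control sequences (the NE and NW
trajectories) are filtered against a constant goal observation — the
sensory input at the end of the NE trajectory — and compared by the
accumulated log likelihood ratio; `|logLR| = 3` (≈95% posterior under
equal priors) counts as a confident decision. The default start
(0.72, 0.25) lies in the north-east pocket of the arena so the goal's
approach is in open view: from the centre, the inner east wall (which
reaches the north border) occludes the goal view along the entire NE
approach and the likelihood ratio then favours the unoccluded alternative
— a geometric visibility requirement on the construction, not a property
of the inference.

**Model selection.** A second environment differs only by swapping the
east/west border colours; a model is trained in each. Filtering one
observation sequence under both models yields a logLR that is carried
almost entirely by vision — the olfactory and touch components are
negligible because those channels are identical across the two
environments (they differ only through the slight divergence of the two
filters' state estimates).

**Planning.** The goal observation holds the environment's olfactory,
touch and visual values at a chosen target location (retina rendered
facing the approach direction) plus a zero speed goal (the agent should be
stationary at the target), constant over the horizon. Planning uses its
own state noise `Q_plan = diag(7e−8, 7e−8, 1e−5, 1e−5)`: position is
essentially noiseless so that inferred motion must be explained through
the control channel (with sizeable position noise the posterior attributes
the motion to state noise and the replayed controls do nothing), while the
moderate speed/heading noise lets the forward sweep explore. The control
random walk is `Q_u = diag(0.1, 0.01)` — acceleration drives are expected
to vary more than heading drives — with control prior `N(0, diag(1, 0.1))`.
Goal attainment is scored by replaying the smoothed control means through
the noiseless dynamics and measuring terminal distance to the target and
terminal speed, against a coast-only baseline.

A single forward–backward sweep with local linearisation follows sensory
gradients: it reaches goals whose sensory code has a usable gradient from
the start (in this arena, targets within the olfactory gradient basin,
roughly within 0.6 of the source, at ranges up to ~0.5) and can park in
local optima of the mismatch landscape for goals behind occluders or in
regions where the sensory landscape is flat. This mirrors the method's
known limitation; multimodal posteriors and iterated re-linearisation are
out of scope.

## What the synthetic environment does and does not show

All data are generated by the package's own environment simulator; there
is no external data. The environment is deliberately minimal: scalar wall
colours instead of textured scenes, a single non-turbulent odour source,
no collision physics (walls affect sensing only — the dynamical model is
free-space motion), and noiseless training exemplars. Passing tests
therefore establish the internal consistency of the inference machinery
and the qualitative phenomena (sensory correction shrinks localisation
error; imagery degrades toward the retinal periphery, where optic flow is
fastest; likelihood ratios implement decisions and environment
recognition; planning-as-inference produces motor sequences), not
performance on real sensory statistics, turbulent olfaction, or cluttered
scenes.

## Problem sizes and determinism

Default simulations use 1000 steps at `dt = 0.01`; the localisation
ablation uses 50 paired trials; the test-suite exercises the full-size
model for the headline checks and 5×5-place/8-HD miniatures elsewhere.
Every random draw flows from one seeded `numpy` generator per run; two
runs with the same configuration and seed produce byte-identical
summaries.

## Known limitations

* The EKF is unimodal: symmetric environments that induce multimodal
  position beliefs will be mis-tracked (no particle filtering).
* The likelihood decomposition is exact but mildly order-dependent.
* Planning is a single forward–backward sweep; goals outside the sensory
  gradient basin of the start state may not be reached.
* The retina samples colour only — no distance attenuation, texture or
  occlusion cues beyond the nearest-wall rule.
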