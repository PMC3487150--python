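# Methods

`actinf` implements two simulators built on the same idea: behavior is
inference.  An agent carries a generative model of its sensations; perception
updates beliefs to minimize variational free energy (an upper bound on
surprise, the negative log evidence), and action samples the world so that
the predictions of those beliefs come true.  Goals enter as *priors* —
a prior over terminal states in the discrete scheme, a prior over fixation
targets in the continuous one — never as reward or cost functions.

## Discrete scheme: planning as inference (`actinf.discrete`)

### Generative model

States, observations and controls are finite.  The model runs backwards in
time ("pullback" parameterization): a terminal prior `c` anchors the chain
and per-control column-stochastic matrices `B_k` give
`P(x_{t-1} | x_t, u_t = k)`; observations follow `P(s_t | x_t) = A x_t` and
controls have a prior `d`.  Hidden controls are *fictive* actions: internal
explanations of transitions, distinct from the action the agent emits.

The trajectory posterior is approximated mean-field, with per-time
categorical marginals `alpha_t` (states, t = 0..T) and `beta_t` (controls,
t = 1..T).  One sweep updates, for t = T-1 down to k+1 (k = time of the last
observation):

    alpha_t  ∝ exp( [likelihood]_t
                    + Σ_j beta_{t+1,j} ln(B_j) · alpha_{t+1}
                    + Σ_j beta_{t,j}  alpha_{t-1} · ln(B_j) )
    beta_t,i ∝ exp( alpha_{t-1}ᵀ ln(B_i) alpha_t + ln d_i )

with every update renormalized.  The likelihood term is inserted only where
an observation exists; observed-time marginals are clamped to their
normalized likelihood columns (exact under the identity likelihood used in
the demonstrations) and `alpha_T` is clamped to `c`, keeping the goal
constraint hard.  `beta_T`, a free variable the backward loop does not
visit, is refreshed at the top of each sweep from `alpha_{T-1}` and
`alpha_T`.  Each update is an exact coordinate minimization of the
free energy, so F is non-increasing sweep over sweep (asserted in tests).

Action selects, among the observations reachable through the sampling
kernel `R(s'|s,a)`, the one expected to be least surprising under the
predicted next-state marginal:
`a = argmax_a Σ_{s'} R(s'|s,a) E_{alpha_{k+1}}[ln A_{s',·}]`.  All argmax
operations break ties to the lowest index, and probabilities are floored at
1e-16 inside logarithms.

### Belief initialization (bridge)

Uniform initialization of the future marginals fails on large models: the
backward wave from the goal and the forward wave from the current state lock
into incompatible trajectories joined by a near-zero-probability "seam", a
local minimum that coordinate updates cannot repair (the expected-log
messages of the mean-field scheme effectively intersect supports, so a bad
joint assignment is locally stable).  Episodes therefore initialize the
unobserved marginals with a *bridge*: the normalized elementwise product of
a forward diffusion of the current state under the control-averaged sampling
kernel and a backward diffusion of the terminal prior under the
control-averaged pullback.  This starts the sweeps on dynamically feasible
mass; the update equations themselves are unchanged.  `init_beliefs`
exposes both modes.

### Exact oracles

Two oracles validate the scheme on small problems.  `exact_smoother`
enumerates every joint state/control trajectory (guarded at 1e6 sequences)
and returns exact marginals and log evidence; `value_iteration` is
finite-horizon backward induction without discounting.  Tests assert:

* free energy ≥ exact negative log evidence, always;
* converged mean-field marginals within KL ≤ 1e-3 of the exact ones on
  weakly coupled toys, and exact recovery of control posteriors when all
  pre-terminal states are observed;
* the agency-free action (posterior propagated through a fixed optimal
  policy) equals the value-iteration action at every visited state on 100
  deterministic toys.

A caveat worth stating plainly: mean field cannot reproduce exact marginals
on *strongly coupled* toys (near-deterministic transitions, hidden interior
states).  There the posterior over trajectories is multimodal and the
factorized approximation concentrates or mis-mixes, with marginal KLs of
order 0.1–5.  The oracle-equivalence tests are therefore run in the two
regimes where the premise holds (weak coupling; fully observed interiors) —
this is a property of the approximation, not of the implementation.

## Mountain car (`actinf.mountain_car`)

The landscape is dimensionless: a parabolic valley `x² + x` (minimum at
-0.5) left of the origin; to the right a constant ramp (slope 0.2) plus a
tall, narrow Gaussian barrier bump (position 0.15, width 0.15, peak slope
~2.4) and a steep containing wall beyond the parking place at +1.  Every
term is multiplied by a single `scale` (default 0.15) that sets the time
scale.  The engine enters as `tanh(a) * action_gain` with
`action_gain = 0.7 * scale`, so the force ceiling (~0.68·scale) is far below
the barrier's peak slope — full throttle from rest cannot climb directly
(enforced by a forward-integration test) — while on the ramp the engine
dominates gravity, so any barrier-crossing momentum can be steered to the
goal.  Friction is linear (0.06).  These constants are this package's own
calibration: they are validated by the qualitative property tests, not by
matching any published values.

Discretization: 32 position bins on [-2, 2] × 32 velocity bins on [-3, 3]
(1024 states, row-major with velocity fastest), five control levels
{-2, -1, 0, 1, 2}, interval Δt = 2 s.  Column `j` of `B_k` bilinearly
splits unit mass over the four bins adjacent to the point reached by
integrating the flow *backwards* over Δt (40 substeps by default; with one
substep this reduces to the one-step form `x_j − f(x_j, a_k)Δt`).  The
sub-stepping matters: at Δt = 2 s a single Euler step aliases fast, remote
states onto spurious predecessors, which both corrupts the environment and
gives the planner illusory shortcuts.  Columns are then blurred with a
Gaussian of 1.0 bins — modeling random fluctuations and the uncertainty
incurred by discretizing — and renormalized.  (0.5-bin smoothing leaves the
pullback support too narrow for reliable mean-field planning; 1.0 passes
robustly across substeps 30–50, sweeps 4–16 and frictions 0.04–0.06.)
Sampling kernels `R_k` are renormalized transposes of `B_k`; states that
appear as nobody's predecessor receive a forward-integrated column.
Back-propagated points leaving the grid are clipped to boundary bins and
counted in the log.

The episode (T = 16 steps, 8 sweeps per step, identity likelihood, uniform
control prior, delta terminal prior on the bin containing (1, 0)) starts
from rest at the origin.  The environment propagates the *modal* next
observation by default; `mode="sampled"` draws from `R` with a seeded
generator.  Under sampled propagation the single-trajectory plan often
derails (only ~2/10 seeds reach the goal) — a real limitation of planning a
single trajectory with this little replanning margin, documented rather
than hidden.

## Continuous scheme: generalized predictive coding (`actinf.filtering`)

A single dynamic level:

    s     = g(x, u) + noise     (precision Π_v per channel)
    dx/dt = f(x, u) + noise     (precision Π_x)
    u     = η_u + noise         (precision Π_u)

with all variables in generalized coordinates of motion (value, velocity,
acceleration, ...; default embedding order n = 3 — the signals simulated
here are smooth and slowly varying, and results are insensitive to n ≥ 2).
Precisions are parameterized as log-precisions, exponentiated once, and
taken identical across orders.  Prediction errors are
`ξ_v = Π_v(s̃ − g̃)`, `ξ_x = Π_x(Dμ̃_x − f̃)`, `ξ_u = Π_u(μ̃_u − η̃_u)`, with
generalized functions evaluated to first order (order m ≥ 1 uses the
order-0 Jacobian; higher-order curvature terms are omitted).  Expectations
follow the gradient flow `μ̃̇ = Dμ̃ − ∂F`, integrated by local linearization
(matrix exponential of the numerically obtained flow Jacobian, computed via
an augmented matrix so singular Jacobians are harmless); explicit Euler at
dt/8 is kept as a cross-check mode.  Note F is a Lyapunov function only for
the order-1 (static) case, where the flow is pure gradient descent; with
generalized motion the D-terms make the descent non-monotone though still
convergent — the tests are phrased accordingly.

Action is a reflex arc: `ȧ = −(∂s̃/∂a)·ξ_v` restricted to proprioceptive
channels, with the sensitivity `∂s̃/∂a` taken as the identity on those
channels (the agent knows which afferents its own motion excites; its
visual consequences are not assumed known).

The conditional precision under the Laplace assumption is the Gauss–Newton
curvature of the Gibbs energy over a designated subset of order-0 states:
`Π = J_gᵀ Π_v J_g + J_fᵀ Π_x J_f + prior terms`.  At zero-residual
configurations this equals the exact Hessian (verified against central
finite differences); `-½ ln|Π|` is the posterior entropy up to constants.

## Visual search (`actinf.saccade`)

The world: a grayscale scene on [-1, 1]² sampled by a 16 × 16 grid of
center-surround channels (difference of Gaussians, σ_center = 0.5 and
σ_surround = 1.0 channel spacings, unit-sum lobes) windowed by a 2-D
Hamming function, covering a fovea of half-extent 0.25.  Sampling is
implemented by pre-filtering the image once and point-sampling bilinearly
(mathematically identical to per-channel convolution, which the tests check
against an explicit kernel sum).  The true gaze obeys `ẋ_p = a − x_p/16`
per 12 ms bin, with sensory noise at log-precision 16 and motion noise at 8.

The agent's model: proprioception is the identity on the believed gaze;
vision is the softmax mixture `Σ_i exp(x_q,i) · r_i(x_p)` of N = 3
hypothesis retinas; the gaze belief decays toward a fixation attractor `u`
with time constant 4 bins; the perceptual log-weights follow the dynamic
softmax flow `ẋ_q = 1 − Σ exp(x_q) − x_q/1024`.  Model log-precisions:
proprioception and state motion 8, vision 4 (vision is deliberately treated
as the less precise channel, so evidence moves the percept, not the gaze
belief).  The exponentials in the flow are clamped at e³⁰ as an overflow
guard; the clamp is inert in the operating region (log-weights live near
[ln(1/N), 0]).  The equilibrium of the perceptual flow satisfies
`Σ exp(x_q) = 1 − x_q/1024` at the symmetric point, i.e. a residual of
|ln(1/3)|/1024 ≈ 1.07e-3 above exact normalization — slightly larger than
the 1e-3 often quoted for this construction, which is why the corresponding
acceptance test is expected to fail by ~7e-5; the flow is implemented as
printed rather than adjusted to pass.

Within a saccade the closed loop runs 16 bins: sense (order 0 plus an
order-1 channel built from the process flow), filter (4 local-linearization
substeps per bin, each with recursive step-halving — the mixture observation
model is strongly nonlinear in gaze and a full-bin step can overshoot into a
divergent linearization during long saccades), then the reflex.  The stiff
proprioceptive reflex (rate e⁸ per bin) is integrated to its fixed point:
the action that makes the sensed gaze velocity equal the predicted one, so
the true gaze tracks the believed gaze, which is drawn to the attractor.

Between saccades, salience is evaluated on a 32 × 32 candidate grid:
for each candidate the gaze state is *counterfactually* set to the
candidate while the current perceptual expectations are held fixed, and
salience is `½ ln|Π|` with the curvature taken over the perceptual states
only (gaze precision is location-independent and would add a constant).
Salience is a function of beliefs alone — the true scene is not an argument
of the computation, and a test asserts bit-identical maps for identical
beliefs.  Inhibition of return then shifts the map to differential salience
(minimum subtracted), multiplies by (1 − R), recenters a Gaussian memory
bump (sd 1/16 of the image size) on the new argmax and adds half the old
memory, clipped to [0, 1]; the just-foveated location is thereby exactly
nulled for the next saccade.  The prior expectation on the fixation
attractor is reset to the argmax with zero higher orders; the filter state
otherwise persists.  The protocol is 8 saccades × 16 bins × 12 ms.

### Fixtures

The hypothesis images are synthetic glyphs: 3–5 Gaussian blobs plus one
soft-edged bar (razor edges make the gaze dynamics needlessly stiff),
128 × 128, with the three hypotheses being the base glyph, its 180° flip
and its 90° rotation — pixel permutations of one another, so they are
equally "rich" but discriminable at the fovea.  Test scenes equal a
hypothesis plus optional seeded noise.  These fixtures emulate the
structure of a face-categorization task (localized high-gradient features,
orientation-variant hypotheses); they do not emulate photographic image
statistics, so passing tests demonstrate the mechanics of salience-driven
evidence accumulation, not performance on natural images.

## Problem sizes and determinism

The demonstrations run at their canonical sizes (1024-state car, 16-step
horizon; 256-channel retina, 1024-candidate salience grid, 8 saccades);
oracle-guarded toys stay at ≤ 4 states, ≤ 3 controls, T ≤ 3.  Every source
of randomness flows through `numpy.random.default_rng(seed)`; modal-mode
episodes and the salience pipeline are fully deterministic.

## Known limitations

* Mean-field marginals are not exact on strongly coupled discrete models
  (see above); the scheme plans well but its uncertainty bookkeeping is
  approximate.
* The discrete environment's modal propagation has bin-scale limit cycles
  (quantization reinjects energy), so "parking" means hovering within the
  goal bin's neighbourhood, and sampled-mode episodes frequently miss the
  16-step deadline.
* The retina's gaze Jacobian uses pre-smoothed gradient images, which is a
  better estimate of the underlying image gradient than the exact derivative
  of the bilinear interpolant but differs from it at the pixel scale
  (~2e-2); the perceptual-weight Jacobians are exact.
* Salience counterfactuals hold current beliefs fixed rather than
  propagating them to a future time; with static scenes and between-saccade
  evaluation the distinction is immaterial here.
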