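"""Discrete-state active inference with hidden control states.

The generative model runs *backwards* in time (a "pullback" parameterization):
a prior ``c`` over the final hidden state anchors the sequence, and per-control
transition matrices ``B_k`` give the distribution of the *previous* state given
the current one, ``P(x_{t-1} | x_t, u_t) = B_{u_t} x_t``.  Observations arise
through a likelihood ``P(s_t | x_t) = A x_t`` and controls carry a prior ``d``.
Costs never appear: goals are priors, and planning is inference.

Beliefs over the hidden-state/control trajectory are optimized under a
mean-field factorization with per-time sufficient statistics ``alpha_t``
(states) and ``beta_t`` (controls) by cyclic coordinate updates
(:func:`variational_sweep`).  Action selects, among the observations reachable
through a sampling kernel ``R``, the one expected to be least surprising under
the predicted posterior (:func:`select_control_action`).

Exact oracles — finite-horizon value iteration (:func:`value_iteration`) and a
brute-force enumeration smoother (:func:`exact_smoother`) — are first-class
citizens here because the scheme's claims (Bellman equivalence of the
agency-free limit, free energy upper-bounding surprise) are checkable on small
problems.

Conventions
-----------
* All stochastic matrices are **column**-stochastic: column ``j`` is the
  distribution over the row index given ``j``.
* All argmax operations break ties toward the lowest index.
* Probabilities are floored at ``PROB_FLOOR`` inside logarithms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

PROB_FLOOR = 1e-16
_COLSUM_TOL = 1e-12


def flog(p: np.ndarray) -> np.ndarray:
    """Logarithm with probabilities floored at ``PROB_FLOOR``."""
    return np.log(np.maximum(p, PROB_FLOOR))


def normalize_columns(M: np.ndarray) -> np.ndarray:
    """Rescale each column of a nonnegative matrix to sum to one.

    Raises
    ------
    ValueError
        If any entry is negative or a column sums to zero (the offending
        column index is reported).
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("matrix has negative entries")
    sums = M.sum(axis=0)
    bad = np.flatnonzero(sums <= 0.0)
    if bad.size:
        raise ValueError(f"column {bad[0]} sums to zero; cannot normalize")
    return M / sums


def check_stochastic(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate a column-stochastic matrix (entries >= 0, columns sum to 1)."""
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError(f"{name} has negative entries")
    if not np.allclose(M.sum(axis=0), 1.0, atol=_COLSUM_TOL, rtol=0.0):
        raise ValueError(f"{name} columns do not sum to 1")
    return M


def _check_prob_vector(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-10):
        raise ValueError(f"{name} is not a probability vector")
    return p


@dataclass
class DiscreteModel:
    """Agency-based generative model ``theta = {A, B_1..B_K, c, d}`` + horizon.

    Parameters
    ----------
    A : (n_obs, n_states) column-stochastic observation likelihood.
    B : list of (n_states, n_states) column-stochastic pullback transitions,
        one per control level; column ``j`` of ``B[k]`` is
        ``P(x_{t-1} | x_t = j, u_t = k)``.
    c : (n_states,) prior over the terminal hidden state (the goal).
    d : (n_controls,) prior over control states.
    T : planning horizon in steps (beliefs span t = 0..T).
    """

    A: np.ndarray
    B: list[np.ndarray]
    c: np.ndarray
    d: np.ndarray
    T: int

    def __post_init__(self) -> None:
        self.A = check_stochastic(self.A, "A")
        self.B = [check_stochastic(Bk, f"B[{k}]") for k, Bk in enumerate(self.B)]
        self.c = _check_prob_vector(self.c, "c")
        self.d = _check_prob_vector(self.d, "d")
        if len(self.d) != len(self.B):
            raise ValueError("len(d) must equal the number of control levels")
        n = self.n_states
        if any(Bk.shape != (n, n) for Bk in self.B) or self.A.shape[1] != n:
            raise ValueError("inconsistent state dimensions")
        if self.c.shape != (n,):
            raise ValueError("c has wrong length")
        if self.T < 1:
            raise ValueError("horizon T must be >= 1")

    @property
    def n_states(self) -> int:
        return self.A.shape[1]

    @property
    def n_obs(self) -> int:
        return self.A.shape[0]

    @property
    def n_controls(self) -> int:
        return len(self.B)


@dataclass
class SamplingKernel:
    """Per-action transition kernels over *observations*.

    ``R[a][s', s]`` is the probability that acting with ``a`` while observing
    ``s`` yields observation ``s'`` next; each ``R[a]`` is column-stochastic.
    """

    R: np.ndarray  # (n_actions, n_obs, n_obs)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 3 or self.R.shape[1] != self.R.shape[2]:
            raise ValueError("R must be (n_actions, n_obs, n_obs)")
        for a in range(self.R.shape[0]):
            check_stochastic(self.R[a], f"R[{a}]")

    @property
    def n_actions(self) -> int:
        return self.R.shape[0]


@dataclass
class RewardSpec:
    """State-wise reward for the classical (Bellman) formulation."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if not np.all(np.isfinite(self.r)):
            raise ValueError("rewards must be finite")


@dataclass
class Beliefs:
    """Mean-field sufficient statistics.

    ``alpha[t]`` (t = 0..T) are marginals over hidden states and ``beta[t-1]``
    (t = 1..T) marginals over controls.
    """

    alpha: np.ndarray  # (T+1, n_states)
    beta: np.ndarray  # (T, n_controls)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name, arr in (("alpha", self.alpha), ("beta", self.beta)):
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-10):
                raise ValueError(f"{name} rows do not sum to 1")

    def copy(self) -> "Beliefs":
        return Beliefs(self.alpha.copy(), self.beta.copy())


@dataclass
class EpisodeTrace:
    """Record of a closed-loop run: T+1 states/observations and T actions."""

    states: list[int] = field(default_factory=list)
    observations: list[int] = field(default_factory=list)
    actions: list[int] = field(default_factory=list)
    beliefs_history: list[Beliefs] = field(default_factory=list)
    free_energy: list[float] = field(default_factory=list)
    #: anticipated trajectories: expected state coordinates under alpha,
    #: one (T+1, coord_dim) array per episode step (when coordinates exist)
    anticipated: list[np.ndarray] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.states)
        if len(self.observations) != n or len(self.actions) != n - 1:
            raise ValueError("trace lengths are inconsistent")


# ---------------------------------------------------------------------------
# Classical oracles
# ---------------------------------------------------------------------------


def value_iteration(
    Tr: np.ndarray, r: RewardSpec | np.ndarray, horizon: int
) -> tuple[np.ndarray, np.ndarray]:
    """Finite-horizon backward induction (no discounting).

    ``Tr[a][x', x]`` are column-stochastic forward transitions.  Returns the
    value function ``V`` of shape (horizon+1, n_states) with ``V[horizon] = r``
    and the greedy policy of shape (horizon, n_states) (``policy[t, x]`` is the
    optimal action at state ``x`` and time ``t``), ties broken to the lowest
    action index.
    """
    rvec = r.r if isinstance(r, RewardSpec) else np.asarray(r, dtype=float)
    Tr = np.asarray(Tr, dtype=float)
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if Tr.shape[1] != rvec.shape[0]:
        raise ValueError("transition/reward dimension mismatch")
    n = rvec.shape[0]
    V = np.zeros((horizon + 1, n))
    policy = np.zeros((horizon, n), dtype=int)
    V[horizon] = rvec
    for t in range(horizon - 1, -1, -1):
        # Q[a, x] = r(x) + sum_{x'} Tr[a][x', x] V_{t+1}(x')
        Q = rvec[None, :] + np.einsum("aij,i->aj", Tr, V[t + 1])
        policy[t] = np.argmax(Q, axis=0)
        V[t] = Q[policy[t], np.arange(n)]
    return V, policy


def agency_free_action(
    posterior_x: np.ndarray,
    policy: np.ndarray,
    Tr: np.ndarray,
    A: np.ndarray,
    R: SamplingKernel,
    s_now: int,
) -> int:
    """Action of the agency-free scheme: pick the action whose expected next
    observation is least surprising under the policy-propagated posterior.

    ``policy`` maps states to actions (a single time slice); the posterior over
    the next hidden state is ``Q(x') = sum_x Tr[policy[x]](x'|x) P(x)`` and the
    returned action maximizes
    ``sum_{s'} R(s'|s_now, a) E_{Q(x')}[ln P(s'|x')]``.
    """
    posterior_x = _check_prob_vector(posterior_x, "posterior_x")
    policy = np.asarray(policy, dtype=int)
    n = posterior_x.shape[0]
    q_next = np.zeros(n)
    for x in range(n):
        if posterior_x[x] > 0:
            q_next += posterior_x[x] * Tr[policy[x]][:, x]
    expected_log_lik = flog(np.asarray(A, dtype=float)) @ q_next  # over s'
    cols = R.R[:, :, s_now]  # (n_actions, n_obs)
    if np.any(cols.sum(axis=1) <= 0):
        raise ValueError("degenerate sampling kernel: no reachable observation")
    objective = cols @ expected_log_lik
    return int(np.argmax(objective))


# ---------------------------------------------------------------------------
# Exact smoother (enumeration oracle)
# ---------------------------------------------------------------------------

ENUMERATION_GUARD = 10**6


def exact_smoother(
    model: DiscreteModel, observations: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact posterior marginals by brute-force enumeration of all sequences.

    Conditions on ``observations[0..k]`` and sums the generative probability
    over every joint hidden-state/control trajectory.  Returns
    ``(alpha_exact, beta_exact, log_evidence)`` where ``alpha_exact`` has shape
    (T+1, n_states), ``beta_exact`` (T, n_controls) and ``log_evidence`` is
    ``ln P(s_0..s_k | m)``.
    """
    T, nx, nu = model.T, model.n_states, model.n_controls
    n_seq = nx ** (T + 1) * nu**T
    if n_seq > ENUMERATION_GUARD:
        raise ValueError(f"enumeration guard exceeded: {n_seq} sequences")
    obs = list(observations)
    logA = flog(model.A)
    logB = np.stack([flog(Bk) for Bk in model.B])
    logc, logd = flog(model.c), flog(model.d)

    states = np.array(list(itertools.product(range(nx), repeat=T + 1)))
    controls = np.array(list(itertools.product(range(nu), repeat=T)))
    # log-prob contributions separable into state-sequence x control-sequence
    logp = np.zeros((states.shape[0], controls.shape[0]))
    for si, xs in enumerate(states):
        lp = logc[xs[T]]
        for t, s in enumerate(obs):
            lp += logA[s, xs[t]]
        logp[si, :] += lp
        for t in range(1, T + 1):
            logp[si, :] += logB[controls[:, t - 1], xs[t - 1], xs[t]]
    logp += logd[controls].sum(axis=1)[None, :]

    log_evidence = float(logsumexp(logp))
    w = np.exp(logp - log_evidence)
    w_states = w.sum(axis=1)
    w_controls = w.sum(axis=0)
    alpha = np.zeros((T + 1, nx))
    beta = np.zeros((T, nu))
    for t in range(T + 1):
        np.add.at(alpha[t], states[:, t], w_states)
    for t in range(T):
        np.add.at(beta[t], controls[:, t], w_controls)
    alpha /= alpha.sum(axis=1, keepdims=True)
    beta /= beta.sum(axis=1, keepdims=True)
    return alpha, beta, log_evidence


# ---------------------------------------------------------------------------
# Variational scheme
# ---------------------------------------------------------------------------


def init_beliefs(
    model: DiscreteModel,
    observations: Sequence[int],
    kernel: SamplingKernel | None = None,
    mode: str = "uniform",
) -> Beliefs:
    """Initial sufficient statistics for the variational sweep.

    Observed times get their normalized likelihood columns, t = T the
    terminal prior, and controls the prior ``d`` throughout.  Unobserved
    interior times are uniform (``mode="uniform"``) or, with
    ``mode="bridge"`` and a sampling kernel, the normalized product of a
    forward diffusion of the last observation (under the control-averaged
    kernel) and a backward diffusion of the terminal prior (under the
    control-averaged pullback).  The bridge concentrates the starting point
    on dynamically feasible trajectories linking the current state to the
    goal, which keeps the coordinate updates out of infeasible local minima
    on large models; the sweeps themselves are unchanged.
    """
    T, nx, nu = model.T, model.n_states, model.n_controls
    alpha = np.full((T + 1, nx), 1.0 / nx)
    k = len(observations) - 1
    for t, s in enumerate(observations):
        if t > T:
            break
        col = model.A[s, :]
        if col.sum() <= 0:
            raise ValueError(f"observation {s} at time {t} has zero likelihood")
        alpha[t] = col / col.sum()
    if mode == "bridge":
        if kernel is None:
            raise ValueError("bridge initialization needs a sampling kernel")
        Bbar = sum(dj * Bj for dj, Bj in zip(model.d, model.B))
        Rbar = sum(dj * Rj for dj, Rj in zip(model.d, kernel.R))
        fwd = np.zeros((T + 1, nx))
        bwd = np.zeros((T + 1, nx))
        fwd[k] = alpha[k] if k >= 0 else np.full(nx, 1.0 / nx)
        for t in range(max(k, 0), T):
            fwd[t + 1] = Rbar @ fwd[t]
        bwd[T] = model.c
        for t in range(T - 1, -1, -1):
            bwd[t] = Bbar @ bwd[t + 1]
        interior = fwd[k + 1 : T] * bwd[k + 1 : T] + PROB_FLOOR
        alpha[k + 1 : T] = interior / interior.sum(axis=1, keepdims=True)
    elif mode != "uniform":
        raise ValueError("mode must be 'uniform' or 'bridge'")
    alpha[T] = model.c
    beta = np.tile(model.d, (T, 1))
    return Beliefs(alpha, beta)


def variational_sweep(
    model: DiscreteModel,
    observations: Sequence[int],
    beliefs: Beliefs,
    n_iterations: int = 8,
    tol: float | None = None,
) -> Beliefs:
    """Mean-field coordinate updates of the trajectory posterior.

    Each full iteration sweeps t from T-1 down to k+1 (k = index of the last
    observation), updating ``alpha_t`` from the control-weighted log-pullback
    messages of its two temporal neighbours, then ``beta_t`` from the expected
    log-transition plus the control prior; ``beta_T`` is refreshed at the top
    of each sweep.  Observed-time marginals stay clamped to their likelihood
    columns and ``alpha_T`` to the terminal prior.  Every update renormalizes.

    ``tol`` enables early stopping when the largest belief change in a full
    sweep falls below it.
    """
    T, nu = model.T, model.n_controls
    k = len(observations) - 1
    if k >= T:
        raise ValueError("observations must not extend beyond T-1")
    logB = [flog(Bk) for Bk in model.B]
    logd = flog(model.d)
    alpha = beliefs.alpha.copy()
    beta = beliefs.beta.copy()
    alpha[T] = model.c  # hard goal constraint

    def _beta_update(t: int) -> None:
        # beta'_ti = exp(alpha_{t-1}^T ln B_i alpha_t + ln d_i), renormalized
        vals = np.array(
            [alpha[t - 1] @ (logB[i] @ alpha[t]) + logd[i] for i in range(nu)]
        )
        vals -= vals.max()
        w = np.exp(vals)
        z = w.sum()
        if z <= 0 or not np.isfinite(z):
            raise ValueError(f"zero normalizer in beta update at t={t}")
        beta[t - 1] = w / z

    for _ in range(n_iterations):
        prev_alpha, prev_beta = alpha.copy(), beta.copy()
        _beta_update(T)
        for t in range(T - 1, k, -1):
            # messages through the pullback: from t+1 (ln B_j . alpha_{t+1})
            # and from t-1 (alpha_{t-1} . ln B_j)
            down = [logB[j] @ alpha[t + 1] for j in range(nu)]
            up = [alpha[t - 1] @ logB[j] for j in range(nu)]
            msg = sum(beta[t, j] * down[j] for j in range(nu))
            msg = msg + sum(beta[t - 1, j] * up[j] for j in range(nu))
            msg -= msg.max()
            w = np.exp(msg)
            z = w.sum()
            if z <= 0 or not np.isfinite(z):
                raise ValueError(f"zero normalizer in alpha update at t={t}")
            alpha[t] = w / z
            vals = np.array([up[i] @ alpha[t] + logd[i] for i in range(nu)])
            vals -= vals.max()
            w = np.exp(vals)
            beta[t - 1] = w / w.sum()
        for t in range(min(k, T - 1), 0, -1):
            _beta_update(t)
        if tol is not None:
            delta = max(
                np.abs(alpha - prev_alpha).max(), np.abs(beta - prev_beta).max()
            )
            if delta < tol:
                break
    return Beliefs(alpha, beta)


def discrete_free_energy(
    model: DiscreteModel, beliefs: Beliefs, observations: Sequence[int]
) -> float:
    """Variational free energy of the mean-field beliefs given observations.

    Gibbs energy (expected negative log generative probability) minus the
    entropy of the factorized posterior; upper-bounds ``-ln P(s_0..s_k | m)``.
    """
    beliefs.validate()
    T, nu = model.T, model.n_controls
    alpha, beta = beliefs.alpha, beliefs.beta
    logA = flog(model.A)
    logB = [flog(Bk) for Bk in model.B]
    energy = -float(alpha[T] @ flog(model.c))
    for t, s in enumerate(observations):
        energy -= float(alpha[t] @ logA[s])
    logd = flog(model.d)
    for t in range(1, T + 1):
        for i in range(nu):
            if beta[t - 1, i] > 0:
                energy -= beta[t - 1, i] * (
                    alpha[t - 1] @ (logB[i] @ alpha[t]) + logd[i]
                )
    def _H(rows: np.ndarray) -> float:
        p = rows[rows > 0]
        return -float(np.sum(p * np.log(p)))

    entropy = _H(alpha) + _H(beta)
    return energy - entropy


def select_control_action(
    beliefs: Beliefs,
    k: int,
    R: SamplingKernel,
    A: np.ndarray,
    s_now: int,
) -> int:
    """Active-inference action: the action whose sampled next observation is
    expected to be least surprising under the predicted state marginal
    ``alpha_{k+1}``.  Ties break to the lowest action index."""
    if k + 1 >= beliefs.alpha.shape[0]:
        raise ValueError("k+1 exceeds the belief horizon")
    expected_log_lik = flog(np.asarray(A, dtype=float)) @ beliefs.alpha[k + 1]
    cols = R.R[:, :, s_now]
    if np.any(cols.sum(axis=1) <= 0):
        raise ValueError("degenerate sampling kernel: no reachable observation")
    return int(np.argmax(cols @ expected_log_lik))


def run_episode(
    model: DiscreteModel,
    R: SamplingKernel,
    start_state: int,
    n_sweeps_per_step: int = 8,
    mode: str = "modal",
    seed: int | None = None,
    state_coords: Callable[[int], np.ndarray] | None = None,
    belief_init: str = "bridge",
) -> EpisodeTrace:
    """Closed-loop episode: alternate belief sweeps and action for T steps.

    The environment is the sampling kernel itself: the next observation is the
    modal state of ``R(.|s, a)`` (``mode="modal"``) or a draw from it
    (``mode="sampled"``, seeded).  Beliefs persist across steps, so updates
    accumulate over both the fast (within-step sweeps) and slow (across-step)
    timescales.  If ``state_coords`` is given, anticipated trajectories
    (expected coordinates under ``alpha``) are stored on each trace snapshot.
    """
    if mode not in ("modal", "sampled"):
        raise ValueError("mode must be 'modal' or 'sampled'")
    if not 0 <= start_state < model.n_obs:
        raise ValueError("start_state out of range")
    rng = np.random.default_rng(seed)
    trace = EpisodeTrace()
    observations: list[int] = [int(start_state)]
    beliefs = init_beliefs(model, observations, kernel=R, mode=belief_init)
    for k in range(model.T):
        # pin the newest observation, keep previously refined beliefs
        col = model.A[observations[k], :]
        beliefs.alpha[k] = col / col.sum()
        beliefs = variational_sweep(
            model, observations, beliefs, n_iterations=n_sweeps_per_step
        )
        a = select_control_action(beliefs, k, R, model.A, observations[k])
        trace.states.append(observations[k])
        trace.observations.append(observations[k])
        trace.actions.append(a)
        trace.beliefs_history.append(beliefs.copy())
        trace.free_energy.append(
            discrete_free_energy(model, beliefs, observations)
        )
        if state_coords is not None:
            coords = np.array(
                [
                    sum(
                        p * state_coords(i)
                        for i, p in enumerate(beliefs.alpha[t])
                        if p > 1e-12
                    )
                    for t in range(model.T + 1)
                ]
            )
            trace.anticipated.append(coords)
        p_next = R.R[a][:, observations[k]]
        if mode == "modal":
            s_next = int(np.argmax(p_next))
        else:
            s_next = int(rng.choice(len(p_next), p=p_next))
        observations.append(s_next)
    trace.states.append(observations[-1])
    trace.observations.append(observations[-1])
    trace.validate()
    return trace


# ---------------------------------------------------------------------------
# Information-theoretic identities
# ---------------------------------------------------------------------------


def entropy_decomposition(
    joint: np.ndarray,
) -> tuple[float, float, float, float]:
    """Entropies (nats) of a joint table over (sensory, hidden) states.

    Returns ``(H_joint, H_S, H_cond, MI)`` where each quantity is computed by
    direct summation, so the chain rule ``H(S, Psi) = H(S) + H(Psi|S)`` and the
    Infomax identity ``H(Psi|S) = H(Psi) - I(Psi;S)`` are nontrivial numerical
    checks rather than definitions.
    """
    joint = np.asarray(joint, dtype=float)
    if np.any(joint < 0):
        raise ValueError("joint has negative entries")
    if not np.isclose(joint.sum(), 1.0, atol=1e-10):
        raise ValueError("joint must sum to 1")
    p_s = joint.sum(axis=1)
    p_psi = joint.sum(axis=0)
    nz = joint > 0
    H_joint = -float(np.sum(joint[nz] * np.log(joint[nz])))
    H_S = -float(np.sum(p_s[p_s > 0] * np.log(p_s[p_s > 0])))
    # conditional entropy by direct summation over the joint support
    ratio = joint / np.where(p_s[:, None] > 0, p_s[:, None], 1.0)
    H_cond = -float(np.sum(joint[nz] * np.log(ratio[nz])))
    indep = p_s[:, None] * p_psi[None, :]
    MI = float(np.sum(joint[nz] * np.log(joint[nz] / indep[nz])))
    return H_joint, H_S, H_cond, MI
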