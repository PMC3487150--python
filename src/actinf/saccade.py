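"""Saccadic visual search as active inference.

An agent views a grayscale scene through a foveated retina (a 16 x 16 grid of
center-surround channels windowed by a 2-D Hamming function) whose center of
gaze is a hidden state driven by action.  Its generative model explains the
visual input as a softmax mixture of N internal hypothesis images sampled at
the believed gaze position; perception is generalized predictive coding
(:mod:`actinf.filtering`) and gaze control is a proprioceptive reflex arc.

Between saccades the agent evaluates *salience* — the log-determinant of the
conditional precision over the perceptual (hypothesis-weight) states it would
obtain if it fixated a candidate location, holding its current beliefs fixed
— on a 32 x 32 grid, suppresses recently foveated locations (inhibition of
return), and resets the prior expectation on the fixation attractor to the
salience maximum.  Salience is a function of beliefs only, never of the true
scene.

Coordinates: origin at the image center, x rightward, y upward, in units of
the image half-width (the image spans [-1, 1]^2).  Time is measured in bins
of 12 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from actinf.filtering import (
    FilterState,
    GeneralizedVector,
    LevelSpec,
    conditional_precision,
    filter_step,
)

Array = np.ndarray

#: log-precisions of the generative *process* (near-noiseless world)
PROCESS_LOG_PREC_SENSORY = 16.0
PROCESS_LOG_PREC_MOTION = 8.0
#: log-precisions assumed by the generative *model*
MODEL_LOG_PREC_PROPRIO = 8.0
MODEL_LOG_PREC_VISUAL = 4.0
MODEL_LOG_PREC_STATES = 8.0
MODEL_LOG_PREC_CONTROLS = 8.0
#: printed perceptual-state decay coefficient
PERCEPTUAL_DECAY = 1.0 / 1024.0
#: gaze time constants, in time bins
PROCESS_GAZE_TC = 16.0
MODEL_GAZE_TC = 4.0


@dataclass
class Image:
    """Grayscale image on [0, 1] with continuous bilinear lookup.

    Lookup outside the support returns the border value.
    """

    values: Array

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("image must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image has non-finite values")
        self._cache: dict = {}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def _to_pixels(self, points: Array) -> Array:
        """Map (x, y) in half-width units to fractional (row, col)."""
        h, w = self.values.shape
        x = points[..., 0]
        y = points[..., 1]
        col = (x + 1.0) / 2.0 * (w - 1)
        row = (1.0 - y) / 2.0 * (h - 1)
        return np.stack([row, col])

    def sample(self, points: Array, values: Array | None = None) -> Array:
        """Bilinear lookup at an (..., 2) array of (x, y) coordinates."""
        src = self.values if values is None else values
        rc = self._to_pixels(np.asarray(points, dtype=float))
        return map_coordinates(src, rc.reshape(2, -1), order=1, mode="nearest").reshape(
            np.asarray(points).shape[:-1]
        )

    def dog_filtered(self, sigma_center_px: float, sigma_surround_px: float):
        """Cached center-surround (difference-of-Gaussians) filtered copy and
        its spatial gradients in half-width units: (F, dF/dx, dF/dy)."""
        key = (round(sigma_center_px, 9), round(sigma_surround_px, 9))
        if key not in self._cache:
            F = gaussian_filter(self.values, sigma_center_px, mode="nearest")
            F = F - gaussian_filter(self.values, sigma_surround_px, mode="nearest")
            h, w = self.values.shape
            dFdr, dFdc = np.gradient(F)
            dFdx = dFdc * (w - 1) / 2.0  # d col / d x
            dFdy = -dFdr * (h - 1) / 2.0  # row decreases with y
            self._cache[key] = (F, dFdx, dFdy)
        return self._cache[key]


@dataclass
class RetinaSpec:
    """Foveated sampling grid of center-surround channels.

    ``n_side ** 2`` channels with offsets on a square grid of half-extent
    ``fov`` (half-width units), difference-of-Gaussians receptive fields
    (sigmas in units of the channel spacing) and a 2-D Hamming window
    modelling the loss of peripheral precision.
    """

    n_side: int = 16
    fov: float = 0.25
    dog_sigma_center: float = 0.5
    dog_sigma_surround: float = 1.0

    def __post_init__(self) -> None:
        if self.n_side < 2:
            raise ValueError("n_side must be >= 2")
        ax = np.linspace(-self.fov, self.fov, self.n_side)
        X, Y = np.meshgrid(ax, ax[::-1])  # row-major, y descending
        self.offsets = np.stack([X.ravel(), Y.ravel()], axis=1)
        ham = np.hamming(self.n_side)
        self.hamming_weights = np.outer(ham, ham).ravel()
        self.spacing = 2.0 * self.fov / (self.n_side - 1)

    @property
    def n_channels(self) -> int:
        return self.n_side**2

    def sigmas_px(self, image: Image) -> tuple[float, float]:
        px_per_unit = (image.shape[1] - 1) / 2.0
        return (
            self.dog_sigma_center * self.spacing * px_per_unit,
            self.dog_sigma_surround * self.spacing * px_per_unit,
        )


@dataclass
class HypothesisSet:
    """The agent's internal images (competing percepts)."""

    images: list[Image]

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("need at least one hypothesis")
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError("all hypothesis images must share dimensions")

    @property
    def n(self) -> int:
        return len(self.images)


@dataclass
class OculomotorState:
    x_p: Array  # (2,) center of gaze

    def __post_init__(self) -> None:
        self.x_p = np.asarray(self.x_p, dtype=float).reshape(2)
        if not np.all(np.isfinite(self.x_p)):
            raise ValueError("gaze must be finite")


@dataclass
class PerceptualState:
    x_q: Array  # (N,) log-weights; exp(x_q) are softmax probabilities

    def softmax(self) -> Array:
        w = np.exp(self.x_q)
        return w / w.sum()


@dataclass
class SalienceMap:
    values: Array  # (n, n) salience on the candidate grid
    ior_memory: Array  # (n, n) inhibition-of-return memory
    argmax_location: Array  # (2,) scene coordinates of the maximum
    candidates: Array  # (n*n, 2) candidate fixations


def sample_retina(
    scene: Image, gaze: OculomotorState | Array, retina: RetinaSpec
) -> Array:
    """Sensory vector: DoG-filtered scene sampled at each channel's offset
    from the gaze center, weighted by the Hamming window."""
    xp = gaze.x_p if isinstance(gaze, OculomotorState) else np.asarray(gaze, float)
    sc, ss = retina.sigmas_px(scene)
    F, _, _ = scene.dog_filtered(sc, ss)
    return scene.sample(retina.offsets + xp, values=F) * retina.hamming_weights


def retina_and_gradient(
    scene: Image, xp: Array, retina: RetinaSpec
) -> tuple[Array, Array]:
    """Retina response and its Jacobian with respect to the gaze (n_ch, 2)."""
    sc, ss = retina.sigmas_px(scene)
    F, dFdx, dFdy = scene.dog_filtered(sc, ss)
    pts = retina.offsets + np.asarray(xp, float)
    h = retina.hamming_weights
    r = scene.sample(pts, values=F) * h
    J = np.stack(
        [scene.sample(pts, values=dFdx) * h, scene.sample(pts, values=dFdy) * h],
        axis=1,
    )
    return r, J


# ---------------------------------------------------------------------------
# Generative process (the world)
# ---------------------------------------------------------------------------


def process_step(
    scene: Image,
    true_state: OculomotorState,
    action: Array,
    dt: float,
    rng: np.random.Generator | None = None,
    retina: RetinaSpec | None = None,
) -> tuple[OculomotorState, Array, Array]:
    """Advance the true gaze one bin and emit sensations.

    ``dx_p/dt = a - x_p/16`` plus motion noise (log-precision 8); sensations
    are the gaze itself (proprioception) and the retinal sample of the scene,
    each with additive noise at log-precision 16.  ``rng=None`` disables
    noise entirely.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    retina = retina or RetinaSpec()
    a = np.asarray(action, dtype=float).reshape(2)
    xp = true_state.x_p
    drift = a - xp / PROCESS_GAZE_TC
    if rng is not None:
        drift = drift + np.exp(-PROCESS_LOG_PREC_MOTION / 2) * rng.standard_normal(2)
    new = OculomotorState(xp + dt * drift)
    s_p = new.x_p.copy()
    s_q = sample_retina(scene, new, retina)
    if rng is not None:
        sig = np.exp(-PROCESS_LOG_PREC_SENSORY / 2)
        s_p = s_p + sig * rng.standard_normal(2)
        s_q = s_q + sig * rng.standard_normal(s_q.shape)
    return new, s_p, s_q


# ---------------------------------------------------------------------------
# Generative model
# ---------------------------------------------------------------------------


@dataclass
class SaccadeSpec(LevelSpec):
    """LevelSpec specialized to the visual-search model (keeps references to
    the hypothesis images and retina so salience can be evaluated)."""

    hyps: HypothesisSet = None  # type: ignore[assignment]
    retina: RetinaSpec = None  # type: ignore[assignment]
    decay: float = PERCEPTUAL_DECAY


def model_functions(
    hyps: HypothesisSet,
    retina: RetinaSpec | None = None,
    n_orders: int = 3,
    decay: float = PERCEPTUAL_DECAY,
    visual_log_prec: float = MODEL_LOG_PREC_VISUAL,
) -> SaccadeSpec:
    """Wire the generative model for the filtering core.

    Hidden states are the believed gaze ``x_p`` (2) and the hypothesis
    log-weights ``x_q`` (N); the hidden control ``u`` (2) is the fixation
    attractor.  Predictions: proprioception is the identity on ``x_p``;
    vision is the softmax mixture of the hypothesis retinas at ``x_p``.
    Flows: ``dx_p/dt = (u - x_p)/4`` and the dynamic-softmax perceptual flow
    ``dx_q/dt = 1 - sum_i exp(x_q_i) - decay * x_q``.
    """
    retina = retina or RetinaSpec()
    N = hyps.n
    n_s = 2 + retina.n_channels

    def _exp(xq: Array) -> Array:
        # overflow guard: log-weights live near [ln(1/N), 0]; the clamp only
        # engages on wild transients and lets the softmax drive recover
        return np.exp(np.clip(xq, -60.0, 30.0))

    def _responses(xp: Array) -> tuple[Array, Array]:
        rs, Js = [], []
        for im in hyps.images:
            r, J = retina_and_gradient(im, xp, retina)
            rs.append(r)
            Js.append(J)
        return np.stack(rs), np.stack(Js)  # (N, n_ch), (N, n_ch, 2)

    def g(x: Array, u: Array) -> Array:
        xp, xq = x[:2], x[2:]
        rs, _ = _responses(xp)
        return np.concatenate([xp, _exp(xq) @ rs])

    def f(x: Array, u: Array) -> Array:
        xp, xq = x[:2], x[2:]
        dxp = (u - xp) / MODEL_GAZE_TC
        dxq = (1.0 - _exp(xq).sum()) - decay * xq
        return np.concatenate([dxp, dxq])

    def gx(x: Array, u: Array) -> Array:
        xp, xq = x[:2], x[2:]
        w = _exp(xq)
        rs, Js = _responses(xp)
        J = np.zeros((n_s, 2 + N))
        J[:2, :2] = np.eye(2)
        J[2:, :2] = np.einsum("i,ics->cs", w, Js)
        J[2:, 2:] = (w[None, :] * rs.T)
        return J

    def gu(x: Array, u: Array) -> Array:
        return np.zeros((n_s, 2))

    def fx(x: Array, u: Array) -> Array:
        xq = x[2:]
        J = np.zeros((2 + N, 2 + N))
        J[:2, :2] = -np.eye(2) / MODEL_GAZE_TC
        J[2:, 2:] = -_exp(xq)[None, :] - decay * np.eye(N)
        return J

    def fu(x: Array, u: Array) -> Array:
        J = np.zeros((2 + N, 2))
        J[:2, :2] = np.eye(2) / MODEL_GAZE_TC
        return J

    log_prec_sensory = np.concatenate(
        [np.full(2, MODEL_LOG_PREC_PROPRIO), np.full(retina.n_channels, visual_log_prec)]
    )
    return SaccadeSpec(
        n_x=2 + N,
        n_u=2,
        n_s=n_s,
        f=f,
        g=g,
        fx=fx,
        fu=fu,
        gx=gx,
        gu=gu,
        log_precisions={
            "sensory": log_prec_sensory,
            "states": MODEL_LOG_PREC_STATES,
            "controls": MODEL_LOG_PREC_CONTROLS,
        },
        control_prior=GeneralizedVector.from_value(np.zeros(2), n_orders),
        n_orders=n_orders,
        hyps=hyps,
        retina=retina,
        decay=decay,
    )


# ---------------------------------------------------------------------------
# Salience
# ---------------------------------------------------------------------------


def candidate_grid(n: int = 32, extent: float = 1.0) -> Array:
    """(n*n, 2) candidate fixations on a uniform grid over the scene
    (bin centers of an n x n partition of [-extent, extent]^2, row-major
    with y descending)."""
    step = 2.0 * extent / n
    ax = -extent + (np.arange(n) + 0.5) * step
    X, Y = np.meshgrid(ax, ax[::-1])
    return np.stack([X.ravel(), Y.ravel()], axis=1)


def salience_map(
    spec: SaccadeSpec,
    filter_state: FilterState,
    candidates: Array | None = None,
) -> SalienceMap:
    """Counterfactual salience over candidate fixations.

    For each candidate the gaze state is replaced by the candidate while the
    current perceptual expectations ``x_q`` are held fixed, and the salience
    is half the log-determinant of the conditional precision over the
    perceptual states (the negative posterior entropy up to constants).
    Depends only on beliefs — the true scene never enters.
    """
    if candidates is None:
        candidates = candidate_grid()
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size == 0:
        raise ValueError("candidates must be nonempty")
    N = spec.hyps.n
    xq = filter_state.mu_x.orders[0][2:]
    w = np.exp(xq)
    pi_v, pi_x, _ = spec.precisions()
    pi_vis = pi_v[2:]
    # candidate-independent curvature from the perceptual flow
    M = -w[None, :] - spec.decay * np.eye(N)  # d(dx_q)/d(x_q)
    C = (M.T * pi_x[2:]) @ M
    # batched retina responses of every hypothesis at every candidate
    n_cand = candidates.shape[0]
    R = np.empty((N, n_cand, spec.retina.n_channels))
    for i, im in enumerate(spec.hyps.images):
        sc, ss = spec.retina.sigmas_px(im)
        F, _, _ = im.dog_filtered(sc, ss)
        pts = candidates[:, None, :] + spec.retina.offsets[None, :, :]
        R[i] = im.sample(pts, values=F) * spec.retina.hamming_weights
    Jg = R.transpose(1, 2, 0) * w[None, None, :]  # (n_cand, n_ch, N)
    P = np.einsum("cki,k,ckj->cij", Jg, pi_vis, Jg) + C[None, :, :]
    sign, logdet = np.linalg.slogdet(P)
    if np.any(sign <= 0):
        P = P + 1e-8 * np.eye(N)[None, :, :]
        sign, logdet = np.linalg.slogdet(P)
    S = 0.5 * logdet
    side = int(round(np.sqrt(n_cand)))
    grid = S.reshape(side, side) if side * side == n_cand else S.reshape(1, -1)
    idx = int(np.argmax(S))
    return SalienceMap(
        values=grid,
        ior_memory=np.zeros_like(grid),
        argmax_location=candidates[idx].copy(),
        candidates=candidates,
    )


def apply_inhibition_of_return(
    S: Array,
    R_prev: Array,
    candidates: Array,
    rho_sigma: float = 0.125,
) -> tuple[Array, Array, Array]:
    """Suppress recently foveated locations and update the memory.

    ``S`` is first shifted to differential salience (minimum subtracted) and
    multiplied entrywise by ``1 - R_prev``; the new memory is a Gaussian bump
    (sd ``rho_sigma``, 1/16 of the image size by default) centered on the new
    argmax plus half the previous memory, clipped to [0, 1].  Returns
    ``(S_final, R_new, argmax_location)``.
    """
    S = np.asarray(S, dtype=float)
    if S.shape != np.asarray(R_prev).shape:
        raise ValueError("salience and memory shapes differ")
    S_diff = S - S.min()
    S_final = S_diff * (1.0 - R_prev)
    idx = int(np.argmax(S_final.ravel()))
    loc = candidates[idx]
    d2 = np.sum((candidates - loc) ** 2, axis=1).reshape(S.shape)
    rho = np.exp(-d2 / (2.0 * rho_sigma**2))
    R_new = np.clip(rho + 0.5 * R_prev, 0.0, 1.0)
    return S_final, R_new, loc.copy()


# ---------------------------------------------------------------------------
# The saccade loop
# ---------------------------------------------------------------------------


@dataclass
class SearchTrace:
    """Per-bin and per-saccade record of a visual search."""

    fixations: list[Array] = field(default_factory=list)
    salience_maps: list[SalienceMap] = field(default_factory=list)
    gaze_true: list[Array] = field(default_factory=list)
    gaze_inferred: list[Array] = field(default_factory=list)
    actions: list[Array] = field(default_factory=list)
    posteriors: list[Array] = field(default_factory=list)
    xq_sd: list[Array] = field(default_factory=list)
    free_energy: list[float] = field(default_factory=list)
    saccade_entropy: list[float] = field(default_factory=list)

    def posterior_entropy(self, p: Array) -> float:
        p = np.clip(np.asarray(p, float), 1e-300, None)
        p = p / p.sum()
        return float(-(p * np.log(p)).sum())


def _adaptive_filter_step(
    spec: SaccadeSpec,
    state: FilterState,
    stv: GeneralizedVector,
    dt: float,
    depth: int = 0,
) -> FilterState:
    """Local-linearization step with recursive halving.

    The mixture observation model is strongly nonlinear in the gaze; during
    long saccades a full step can overshoot into a region whose linearization
    diverges.  A step whose result is non-finite or implausibly large is
    retried as two half steps (up to 2^6 subdivisions).
    """
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            new = filter_step(spec, state, stv, dt, method="ll")
        if np.abs(new.mu_x.orders).max() < 1e3:
            return new
    except FloatingPointError:
        pass
    if depth >= 6:
        raise FloatingPointError("filter step diverged at the smallest step size")
    half = _adaptive_filter_step(spec, state, stv, dt / 2, depth + 1)
    return _adaptive_filter_step(spec, half, stv, dt / 2, depth + 1)


def _reflex_action(spec: SaccadeSpec, state: FilterState, s_p: Array) -> Array:
    """Stationary point of the stiff proprioceptive reflex arc.

    The reflex ODE ``da/dt = -xi_v'`` is linear in the action with rate
    ``exp(proprio log-precision)`` — orders of magnitude faster than a 12 ms
    bin — so it is integrated to its fixed point: the action that makes the
    sensed gaze velocity equal the predicted one.
    """
    mu_vel = state.mu_x.orders[1][:2]
    return np.asarray(s_p, float) / PROCESS_GAZE_TC + mu_vel


def saccade_search(
    scene: Image,
    hyps: HypothesisSet,
    n_saccades: int = 8,
    bins_per_saccade: int = 16,
    dt_ms: float = 12.0,
    seed: int | None = None,
    retina: RetinaSpec | None = None,
    n_salience: int = 32,
    n_orders: int = 3,
    noise: bool = True,
    ll_substeps: int = 4,
) -> SearchTrace:
    """Simulate a visual search: filtering within saccades, salience between.

    Each saccade integrates the closed perception-action loop for
    ``bins_per_saccade`` time bins (``dt_ms`` each, 12 ms by default), then
    computes a salience map over ``n_salience**2`` candidate fixations,
    applies inhibition of return and resets the fixation prior to the
    salience maximum.  ``dt_ms`` is metadata: all time constants are
    expressed per bin.
    """
    if n_saccades < 1:
        raise ValueError("n_saccades must be >= 1")
    retina = retina or RetinaSpec()
    spec = model_functions(hyps, retina, n_orders=n_orders)
    rng = np.random.default_rng(seed) if noise else None
    N = hyps.n
    state = FilterState(
        mu_x=GeneralizedVector.from_value(
            np.concatenate([np.zeros(2), np.full(N, np.log(1.0 / N))]), n_orders
        ),
        mu_u=GeneralizedVector.from_value(np.zeros(2), n_orders),
        action=np.zeros(2),
    )
    true_state = OculomotorState(np.zeros(2))
    candidates = candidate_grid(n_salience)
    R_ior = np.zeros((n_salience, n_salience))
    trace = SearchTrace()
    dt = 1.0  # one time bin
    for k in range(n_saccades):
        for _ in range(bins_per_saccade):
            true_state, s_p, s_q = process_step(
                scene, true_state, state.action, dt, rng=rng, retina=retina
            )
            # generalized sensory input: order 1 from the process flow
            r_true, J_true = retina_and_gradient(scene, true_state.x_p, retina)
            xdot = state.action - true_state.x_p / PROCESS_GAZE_TC
            s_tilde = np.zeros((n_orders, spec.n_s))
            s_tilde[0] = np.concatenate([s_p, s_q])
            if n_orders > 1:
                s_tilde[1] = np.concatenate([xdot, J_true @ xdot])
            stv = GeneralizedVector(s_tilde)
            # several local-linearization steps per bin: the mixture
            # observation model is strongly nonlinear in the gaze, and one
            # step per 12 ms bin can overshoot during large saccades
            for _ in range(ll_substeps):
                state = _adaptive_filter_step(spec, state, stv, dt / ll_substeps)
            state.action = _reflex_action(spec, state, s_p)
            w = np.exp(state.mu_x.orders[0][2:])
            trace.posteriors.append(w / w.sum())
            trace.gaze_true.append(true_state.x_p.copy())
            trace.gaze_inferred.append(state.mu_x.orders[0][:2].copy())
            trace.actions.append(state.action.copy())
            trace.free_energy.append(state.free_energy)
            P = conditional_precision(
                spec,
                state.mu_x.orders[0],
                state.mu_u.orders[0],
                subset=np.arange(2, 2 + N),
            )
            trace.xq_sd.append(np.sqrt(np.diag(np.linalg.inv(P))))
        smap = salience_map(spec, state, candidates)
        S_final, R_ior, loc = apply_inhibition_of_return(
            smap.values, R_ior, candidates
        )
        smap.values = S_final
        smap.ior_memory = R_ior.copy()
        smap.argmax_location = loc
        trace.salience_maps.append(smap)
        trace.fixations.append(loc.copy())
        trace.saccade_entropy.append(trace.posterior_entropy(trace.posteriors[-1]))
        # prior reset: the fixation attractor jumps to the salience maximum
        spec.control_prior = GeneralizedVector.from_value(loc, n_orders)
    return trace
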