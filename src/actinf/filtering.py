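"""Generalized predictive coding: free-energy gradient flows in generalized
coordinates of motion.

A single-level dynamic generative model

.. code-block:: text

    s     = g(x, u) + noise        precision  Pi_v  (per sensory channel)
    dx/dt = f(x, u) + noise        precision  Pi_x
    u     = eta_u  + noise         precision  Pi_u  (prior on hidden controls)

is inverted by integrating the gradient flow
``d(mu~)/dt = D mu~ - dF/d(mu~)`` where ``mu~`` stacks conditional
expectations in generalized coordinates (value, velocity, acceleration, ...),
``D`` is the shift operator and ``F`` the (Laplace) free energy whose gradient
is assembled from precision-weighted prediction errors.  Action descends the
same free energy through its effect on sensations (a reflex arc on
proprioceptive prediction errors).  Generalized nonlinear functions are
evaluated to first order: order ``m >= 1`` uses the Jacobian at order 0.

The integrator is local linearization over each time bin (matrix exponential
of the flow Jacobian); a plain explicit-Euler mode with 8 substeps is kept as
a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import expm

Array = np.ndarray


@dataclass
class GeneralizedVector:
    """A variable and its temporal derivatives: ``orders[m]`` is the m-th
    derivative, all sharing one dimensionality."""

    orders: Array  # (n_orders, dim)

    def __post_init__(self) -> None:
        self.orders = np.atleast_2d(np.asarray(self.orders, dtype=float))

    @classmethod
    def from_value(cls, value: Array, n_orders: int) -> "GeneralizedVector":
        value = np.atleast_1d(np.asarray(value, dtype=float))
        out = np.zeros((n_orders, value.shape[0]))
        out[0] = value
        return cls(out)

    @property
    def n_orders(self) -> int:
        return self.orders.shape[0]

    @property
    def dim(self) -> int:
        return self.orders.shape[1]

    def value(self) -> Array:
        return self.orders[0]


def shift(v: GeneralizedVector | Array) -> GeneralizedVector | Array:
    """The differential operator ``D``: order ``i`` of the output is order
    ``i+1`` of the input; the top order becomes zero."""
    if isinstance(v, GeneralizedVector):
        return GeneralizedVector(shift(v.orders))
    out = np.zeros_like(v)
    out[:-1] = v[1:]
    return out


def shift_T(v: Array) -> Array:
    """Adjoint of :func:`shift`: shifts orders down, zero into order 0."""
    out = np.zeros_like(v)
    out[1:] = v[:-1]
    return out


def _fd_jacobian(fun: Callable[[Array], Array], x0: Array, eps: float = 1e-6) -> Array:
    y0 = np.atleast_1d(fun(x0))
    J = np.zeros((y0.shape[0], x0.shape[0]))
    for i in range(x0.shape[0]):
        dx = np.zeros_like(x0)
        dx[i] = eps
        J[:, i] = (np.atleast_1d(fun(x0 + dx)) - np.atleast_1d(fun(x0 - dx))) / (
            2 * eps
        )
    return J


@dataclass
class LevelSpec:
    """Specification of the generative model (one dynamic level).

    ``log_precisions`` maps ``"sensory"``, ``"states"`` and ``"controls"`` to
    scalars or per-dimension vectors of log-precisions (exponentiated once).
    ``control_prior`` is the generalized prior expectation ``eta_u`` over the
    hidden controls.  Jacobian callables are optional; central finite
    differences are used when they are omitted.
    """

    n_x: int
    n_u: int
    n_s: int
    f: Callable[[Array, Array], Array]
    g: Callable[[Array, Array], Array]
    log_precisions: dict[str, float | Array]
    control_prior: GeneralizedVector
    fx: Callable[[Array, Array], Array] | None = None
    fu: Callable[[Array, Array], Array] | None = None
    gx: Callable[[Array, Array], Array] | None = None
    gu: Callable[[Array, Array], Array] | None = None
    n_orders: int = 3

    def precisions(self) -> tuple[Array, Array, Array]:
        def _vec(key: str, dim: int) -> Array:
            lp = np.asarray(self.log_precisions.get(key, 0.0), dtype=float)
            return np.exp(np.broadcast_to(lp, (dim,)).astype(float))

        return (
            _vec("sensory", self.n_s),
            _vec("states", self.n_x),
            _vec("controls", self.n_u),
        )

    def jacobians(self, x: Array, u: Array) -> tuple[Array, Array, Array, Array]:
        """(df/dx, df/du, dg/dx, dg/du) at order 0."""
        Fx = self.fx(x, u) if self.fx else _fd_jacobian(lambda z: self.f(z, u), x)
        Fu = self.fu(x, u) if self.fu else _fd_jacobian(lambda z: self.f(x, z), u)
        Gx = self.gx(x, u) if self.gx else _fd_jacobian(lambda z: self.g(z, u), x)
        Gu = self.gu(x, u) if self.gu else _fd_jacobian(lambda z: self.g(x, z), u)
        return (
            np.asarray(Fx, float).reshape(self.n_x, self.n_x),
            np.asarray(Fu, float).reshape(self.n_x, self.n_u),
            np.asarray(Gx, float).reshape(self.n_s, self.n_x),
            np.asarray(Gu, float).reshape(self.n_s, self.n_u),
        )

    def validate_gradients(self, x: Array, u: Array, tol: float = 1e-5) -> None:
        """Check supplied Jacobians against finite differences."""
        supplied = self.jacobians(x, u)
        numeric = LevelSpec(
            self.n_x, self.n_u, self.n_s, self.f, self.g,
            self.log_precisions, self.control_prior, n_orders=self.n_orders,
        ).jacobians(x, u)
        for name, a, b in zip("fx fu gx gu".split(), supplied, numeric):
            if not np.allclose(a, b, atol=tol, rtol=tol):
                raise ValueError(f"supplied Jacobian {name} disagrees with finite differences")


@dataclass
class FilterState:
    """Conditional expectations, action and the latest prediction errors."""

    mu_x: GeneralizedVector
    mu_u: GeneralizedVector
    action: Array = field(default_factory=lambda: np.zeros(0))
    xi_v: Array | None = None
    xi_x: Array | None = None
    xi_u: Array | None = None
    free_energy: float = np.nan

    @classmethod
    def zeros(cls, spec: LevelSpec, n_action: int = 0) -> "FilterState":
        return cls(
            mu_x=GeneralizedVector(np.zeros((spec.n_orders, spec.n_x))),
            mu_u=GeneralizedVector(spec.control_prior.orders.copy()),
            action=np.zeros(n_action),
        )


def generalized_predictions(
    spec: LevelSpec, mu_x: Array, mu_u: Array
) -> tuple[Array, Array, tuple[Array, Array, Array, Array]]:
    """Evaluate ``g`` and ``f`` in generalized coordinates (first-order chain
    rule for orders >= 1).  Returns (g_tilde, f_tilde, jacobians)."""
    n = mu_x.shape[0]
    x0, u0 = mu_x[0], mu_u[0]
    Fx, Fu, Gx, Gu = spec.jacobians(x0, u0)
    g_t = np.zeros((n, spec.n_s))
    f_t = np.zeros((n, spec.n_x))
    g_t[0] = np.atleast_1d(spec.g(x0, u0))
    f_t[0] = np.atleast_1d(spec.f(x0, u0)) if spec.n_x else np.zeros(0)
    for m in range(1, n):
        g_t[m] = Gx @ mu_x[m] + Gu @ mu_u[m]
        f_t[m] = Fx @ mu_x[m] + Fu @ mu_u[m]
    return g_t, f_t, (Fx, Fu, Gx, Gu)


def prediction_errors(
    spec: LevelSpec, state: FilterState, s_tilde: GeneralizedVector
) -> tuple[Array, Array, Array]:
    """Precision-weighted prediction errors (xi_v, xi_x, xi_u).

    ``xi_v = Pi_v (s~ - g~)``, ``xi_x = Pi_x (D mu~_x - f~)``,
    ``xi_u = Pi_u (mu~_u - eta~_u)``; shapes (n_orders, dim).
    """
    pi_v, pi_x, pi_u = spec.precisions()
    mu_x, mu_u = state.mu_x.orders, state.mu_u.orders
    g_t, f_t, _ = generalized_predictions(spec, mu_x, mu_u)
    xi_v = pi_v * (s_tilde.orders - g_t)
    xi_x = pi_x * (shift(mu_x) - f_t)
    eta = spec.control_prior.orders
    xi_u = pi_u * (mu_u - eta)
    return xi_v, xi_x, xi_u


def gibbs_energy(
    spec: LevelSpec, mu_x: Array, mu_u: Array, s_tilde: Array
) -> float:
    """Quadratic Gibbs energy (negative log joint up to constants)."""
    pi_v, pi_x, pi_u = spec.precisions()
    g_t, f_t, _ = generalized_predictions(spec, mu_x, mu_u)
    ev = s_tilde - g_t
    ex = shift(mu_x) - f_t
    eu = mu_u - spec.control_prior.orders
    return 0.5 * float(
        np.sum(pi_v * ev**2) + np.sum(pi_x * ex**2) + np.sum(pi_u * eu**2)
    )


def _mu_flow(
    spec: LevelSpec, mu_x: Array, mu_u: Array, s_tilde: Array
) -> tuple[Array, Array]:
    """Generalized gradient-descent flow of the expectations."""
    pi_v, pi_x, pi_u = spec.precisions()
    g_t, f_t, (Fx, Fu, Gx, Gu) = generalized_predictions(spec, mu_x, mu_u)
    xi_v = pi_v * (s_tilde - g_t)
    xi_x = pi_x * (shift(mu_x) - f_t)
    xi_u = pi_u * (mu_u - spec.control_prior.orders)
    dmu_x = shift(mu_x) + xi_v @ Gx + xi_x @ Fx - shift_T(xi_x)
    dmu_u = shift(mu_u) + xi_v @ Gu + xi_x @ Fu - xi_u
    return dmu_x, dmu_u


def filter_step(
    spec: LevelSpec,
    state: FilterState,
    s_tilde: GeneralizedVector,
    dt: float,
    method: str = "ll",
) -> FilterState:
    """Advance the conditional expectations by one time bin of length ``dt``.

    ``method="ll"`` uses local linearization, ``Delta z = (e^{J dt} - I)
    J^{-1} z_dot`` with the flow Jacobian obtained by finite differences
    (computed via an augmented matrix exponential, so a singular ``J`` is
    harmless); ``method="euler"`` takes 8 explicit substeps.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    nx, nu, n = spec.n_x, spec.n_u, spec.n_orders
    s = s_tilde.orders

    def pack(mx: Array, mu: Array) -> Array:
        return np.concatenate([mx.ravel(), mu.ravel()])

    def unpack(z: Array) -> tuple[Array, Array]:
        return z[: n * nx].reshape(n, nx), z[n * nx :].reshape(n, nu)

    def flow(z: Array) -> Array:
        dmx, dmu = _mu_flow(spec, *unpack(z), s)
        return pack(dmx, dmu)

    z0 = pack(state.mu_x.orders, state.mu_u.orders)
    if method == "euler":
        z = z0
        for _ in range(8):
            z = z + (dt / 8.0) * flow(z)
    elif method == "ll":
        F0 = flow(z0)
        J = _fd_jacobian(flow, z0)
        dim = z0.shape[0]
        aug = np.zeros((dim + 1, dim + 1))
        aug[:dim, :dim] = J * dt
        aug[:dim, dim] = F0 * dt
        z = z0 + expm(aug)[:dim, dim]
    else:
        raise ValueError("method must be 'll' or 'euler'")
    if not np.all(np.isfinite(z)):
        raise FloatingPointError(
            f"non-finite expectations after filter step (mu_x={unpack(z)[0]!r})"
        )
    mu_x, mu_u = unpack(z)
    new = FilterState(
        GeneralizedVector(mu_x), GeneralizedVector(mu_u), state.action.copy()
    )
    new.xi_v, new.xi_x, new.xi_u = prediction_errors(spec, new, s_tilde)
    new.free_energy = gibbs_energy(spec, mu_x, mu_u, s)
    return new


def action_step(
    spec: LevelSpec,
    state: FilterState,
    s_tilde: GeneralizedVector,
    sensitivity: Array,
    dt: float,
) -> Array:
    """Reflex-arc action update: ``a_dot = -(ds~/da) . xi_v`` restricted to the
    channels (typically proprioceptive) encoded in ``sensitivity``.

    ``sensitivity`` has shape (n_orders, n_s, n_a): entry ``[m, i, j]`` is the
    sensitivity of the m-th derivative of sensory channel ``i`` to action
    ``j``.  Returns the updated action vector (explicit Euler over ``dt``).
    """
    xi_v, _, _ = prediction_errors(spec, state, s_tilde)
    sens = np.asarray(sensitivity, dtype=float)
    a_dot = -np.einsum("mi,mij->j", xi_v, sens)
    return state.action + dt * a_dot


def proprio_sensitivity(
    spec: LevelSpec, proprio_idx: np.ndarray, n_action: int, order: int = 1
) -> Array:
    """Identity sensitivity of the given sensory channels to action at one
    generalized order (the agent knows acting excites those afferents)."""
    S = np.zeros((spec.n_orders, spec.n_s, n_action))
    for j, i in enumerate(np.atleast_1d(proprio_idx)[:n_action]):
        S[order, i, j] = 1.0
    return S


def conditional_precision(
    spec: LevelSpec,
    mu_x: Array,
    mu_u: Array,
    subset: np.ndarray | None = None,
    jitter: float = 1e-8,
) -> Array:
    """Gauss-Newton curvature of the Gibbs energy over designated states.

    The designated states index the concatenated order-0 vector ``[x, u]``
    (default: all of it).  The curvature sums ``J^T Pi J`` over the sensory
    and dynamics terms plus the control-prior precision for ``u`` entries;
    a diagonal ``jitter`` is added if the result is not positive definite.
    Under the Laplace assumption ``-1/2 ln|Pi|`` is the posterior entropy up
    to constants, so this is the currency of salience.
    """
    pi_v, pi_x, pi_u = spec.precisions()
    Fx, Fu, Gx, Gu = spec.jacobians(np.asarray(mu_x, float), np.asarray(mu_u, float))
    if not (np.all(np.isfinite(Gx)) and np.all(np.isfinite(Gu))):
        raise FloatingPointError("non-finite observation Jacobian")
    Gz = np.concatenate([Gx, Gu], axis=1)
    Fz = np.concatenate([Fx, Fu], axis=1)
    prior = np.concatenate([np.zeros(spec.n_x), pi_u])
    P = (Gz.T * pi_v) @ Gz + (Fz.T * pi_x) @ Fz + np.diag(prior)
    if subset is None:
        subset = np.arange(spec.n_x + spec.n_u)
    subset = np.atleast_1d(np.asarray(subset, dtype=int))
    if subset.size == 0:
        raise ValueError("designated-state subset must be nonempty")
    P = P[np.ix_(subset, subset)]
    P = 0.5 * (P + P.T)
    try:
        np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        P = P + jitter * np.eye(P.shape[0])
    return P
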