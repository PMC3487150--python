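"""Continuous mountain-car dynamics and their discretization.

A car sits in a valley (potential minimum near position -0.5) with a parking
place on the hill to its right at position +1.  The engine acts through a
bounded squashing function (tanh), and is too weak to climb the right-hand
slope directly from rest: the only route to the goal is a leftward excursion
to gather momentum.  The continuous flow is discretized onto a grid of
position/velocity bins as *pullback* transition matrices: column ``j`` of
``B_k`` spreads probability over the states from which the car could have come
one time step earlier under control level ``k`` (bilinear mass-splitting over
the four neighbouring bins, optionally Gaussian-smoothed to model random
fluctuations).  The sampling kernels ``R_k`` used to generate the environment
are the renormalized transposes of the ``B_k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter

from actinf.discrete import DiscreteModel, SamplingKernel, normalize_columns

logger = logging.getLogger(__name__)

# Potential-shape constants (dimensionless).  The left branch is the parabola
# x^2 + x with its valley at -0.5.  The right branch is a gentle constant ramp
# plus a tall, narrow Gaussian barrier bump just right of the origin (peak
# slope ~ 2.4, far above the engine ceiling tanh(2) * GAIN_RATIO ~ 0.68, so
# the hill cannot be climbed directly) and a steep containing wall beyond the
# parking place at x = 1.  On the ramp the engine dominates gravity, so once
# the barrier is crossed with momentum the approach to the goal is
# controllable at any speed.
GAIN_RATIO = 0.7  # action_gain / scale
_RAMP = 0.2
_BUMP_POS = 0.15
_BUMP_WIDTH = 0.15
_BUMP_AMP = (1.0 - _RAMP) * np.exp((_BUMP_POS / _BUMP_WIDTH) ** 2)  # slope continuity at 0
_WALL_POS = 1.1
_WALL_COEF = 8.0


def potential_slope(x: np.ndarray | float, scale: float = 1.0) -> np.ndarray:
    """Gradient dH/dx of :func:`potential_height` (gravitational force)."""
    x = np.asarray(x, dtype=float)
    left = 2.0 * x + 1.0
    right = (
        _RAMP
        + _BUMP_AMP * np.exp(-(((x - _BUMP_POS) / _BUMP_WIDTH) ** 2))
        + _WALL_COEF * np.clip(x - _WALL_POS, 0.0, None) ** 3
    )
    return scale * np.where(x < 0, left, right)


def potential_height(x: np.ndarray | float, scale: float = 1.0) -> np.ndarray:
    """Height of the landscape at position ``x`` (times ``scale``)."""
    from scipy.special import erf

    x = np.asarray(x, dtype=float)
    left = x**2 + x
    w = _BUMP_WIDTH
    right = (
        _RAMP * x
        + _BUMP_AMP
        * (w * np.sqrt(np.pi) / 2.0)
        * (erf((x - _BUMP_POS) / w) + erf(_BUMP_POS / w))
        + _WALL_COEF / 4.0 * np.clip(x - _WALL_POS, 0.0, None) ** 4
    )
    return scale * np.where(x < 0, left, right)


@dataclass
class CarState:
    position: float
    velocity: float

    def as_array(self) -> np.ndarray:
        return np.array([self.position, self.velocity], dtype=float)


@dataclass
class CarDynamics:
    """Equations of motion of the car.

    ``v' = tanh(a) * action_gain - dH/dx - friction * v`` with ``x' = v``.
    ``scale`` multiplies the landscape; the defaults are calibrated so that
    (i) full throttle cannot climb the right slope directly from rest and
    (ii) a single leftward swing suffices within a 16-step, 2 s-per-step
    episode (both properties are enforced by tests, not by constants copied
    from anywhere).
    """

    scale: float = 0.15
    friction: float = 0.06
    action_gain: float | None = None  # defaults to GAIN_RATIO * scale
    dt: float = 2.0
    potential: Callable[[np.ndarray], np.ndarray] = field(default=None)  # type: ignore[assignment]
    potential_grad: Callable[[np.ndarray], np.ndarray] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.action_gain is None:
            self.action_gain = GAIN_RATIO * self.scale
        if self.potential is None:
            self.potential = lambda x: potential_height(x, self.scale)
        if self.potential_grad is None:
            self.potential_grad = lambda x: potential_slope(x, self.scale)


def car_flow(
    x: CarState | np.ndarray, a: float, dynamics: CarDynamics
) -> np.ndarray:
    """Continuous flow ``(dx/dt, dv/dt)`` at state ``x`` under action ``a``."""
    arr = x.as_array() if isinstance(x, CarState) else np.asarray(x, float)
    pos, vel = arr[..., 0], arr[..., 1]
    acc = (
        np.tanh(a) * dynamics.action_gain
        - dynamics.potential_grad(pos)
        - dynamics.friction * vel
    )
    return np.stack([np.asarray(vel, float), np.asarray(acc, float)], axis=-1)


def integrate_car(
    dynamics: CarDynamics,
    start: CarState,
    action: float | Callable[[float], float],
    duration: float,
    dt: float = 0.01,
) -> np.ndarray:
    """Forward-Euler rollout of the continuous dynamics (oracle for tests).

    Returns an array of shape (n_steps+1, 2) of (position, velocity).
    """
    n = int(round(duration / dt))
    out = np.empty((n + 1, 2))
    out[0] = start.as_array()
    a_of_t = action if callable(action) else (lambda t: action)
    for i in range(n):
        out[i + 1] = out[i] + dt * car_flow(out[i], a_of_t(i * dt), dynamics)
    return out


@dataclass
class GridSpec:
    """Discretization grid: position x velocity bins plus control levels.

    State index ``i = i_pos * n_vel + i_vel`` (row-major, velocity fastest).
    Bin centers are at ``lo + (i + 0.5) * width``.
    """

    n_pos: int = 32
    pos_range: tuple[float, float] = (-2.0, 2.0)
    n_vel: int = 32
    vel_range: tuple[float, float] = (-3.0, 3.0)
    control_values: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_vel < 2:
            raise ValueError("need at least 2 bins per dimension")
        cv = tuple(self.control_values)
        if sorted(set(cv)) != list(cv):
            raise ValueError("control_values must be sorted and distinct")
        self.control_values = cv

    @property
    def n_states(self) -> int:
        return self.n_pos * self.n_vel

    @property
    def pos_width(self) -> float:
        return (self.pos_range[1] - self.pos_range[0]) / self.n_pos

    @property
    def vel_width(self) -> float:
        return (self.vel_range[1] - self.vel_range[0]) / self.n_vel

    def pos_centers(self) -> np.ndarray:
        lo, _ = self.pos_range
        return lo + (np.arange(self.n_pos) + 0.5) * self.pos_width

    def vel_centers(self) -> np.ndarray:
        lo, _ = self.vel_range
        return lo + (np.arange(self.n_vel) + 0.5) * self.vel_width

    def all_coords(self) -> np.ndarray:
        """(n_states, 2) array of bin-center (position, velocity)."""
        P, V = np.meshgrid(self.pos_centers(), self.vel_centers(), indexing="ij")
        return np.stack([P.ravel(), V.ravel()], axis=1)


def state_coords(grid: GridSpec, i: int) -> CarState:
    """Bin-center coordinates of state index ``i``."""
    if not 0 <= i < grid.n_states:
        raise IndexError(f"state index {i} out of range")
    ip, iv = divmod(int(i), grid.n_vel)
    return CarState(grid.pos_centers()[ip], grid.vel_centers()[iv])


def control_value(grid: GridSpec, k: int) -> float:
    """Real-valued action associated with control level ``k``."""
    if not 0 <= k < len(grid.control_values):
        raise IndexError(f"control index {k} out of range")
    return float(grid.control_values[k])


def nearest_state_index(grid: GridSpec, state: CarState | np.ndarray) -> int:
    """Index of the bin containing (position, velocity), clipped to the grid."""
    arr = state.as_array() if isinstance(state, CarState) else np.asarray(state)
    ip = int(np.clip((arr[0] - grid.pos_range[0]) // grid.pos_width, 0, grid.n_pos - 1))
    iv = int(np.clip((arr[1] - grid.vel_range[0]) // grid.vel_width, 0, grid.n_vel - 1))
    return ip * grid.n_vel + iv


def _bilinear_masses(
    grid: GridSpec, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split unit mass at continuous ``points`` (n, 2) over the 4 adjacent
    bin centers.  Returns (pos indices, vel indices, weights), each (n, 4)."""
    fp = (points[:, 0] - grid.pos_range[0]) / grid.pos_width - 0.5
    fv = (points[:, 1] - grid.vel_range[0]) / grid.vel_width - 0.5
    fp = np.clip(fp, 0.0, grid.n_pos - 1.0)
    fv = np.clip(fv, 0.0, grid.n_vel - 1.0)
    p0 = np.floor(fp).astype(int)
    v0 = np.floor(fv).astype(int)
    p0 = np.minimum(p0, grid.n_pos - 2) if grid.n_pos > 1 else p0
    v0 = np.minimum(v0, grid.n_vel - 2) if grid.n_vel > 1 else v0
    wp = fp - p0
    wv = fv - v0
    ips = np.stack([p0, p0 + 1, p0, p0 + 1], axis=1)
    ivs = np.stack([v0, v0, v0 + 1, v0 + 1], axis=1)
    w = np.stack(
        [(1 - wp) * (1 - wv), wp * (1 - wv), (1 - wp) * wv, wp * wv], axis=1
    )
    return ips, ivs, w


def _propagate(
    coords: np.ndarray,
    a: float,
    dynamics: CarDynamics,
    n_substeps: int,
    direction: float,
) -> np.ndarray:
    """Integrate the flow over one discrete interval (vectorized over states).

    ``direction=-1`` runs time backwards (the pullback), ``+1`` forwards.
    A single substep reduces to the one-step Euler form
    ``x -+ f(x, a) * dt``.
    """
    pts = coords.copy()
    h = dynamics.dt / n_substeps
    # keep runaway (off-grid) points finite; they are clipped to boundary bins
    lo = np.array([-8.0, -12.0])
    hi = np.array([8.0, 12.0])
    for _ in range(n_substeps):
        pts = np.clip(pts + direction * h * car_flow(pts, a, dynamics), lo, hi)
    return pts


def build_pullback(
    dynamics: CarDynamics,
    grid: GridSpec,
    smoothing_sigma: float = 1.0,
    n_substeps: int = 40,
) -> tuple[list[np.ndarray], SamplingKernel]:
    """Discretize the flow into pullback matrices and a sampling kernel.

    For control level ``k``, column ``j`` of ``B_k`` places mass on the bins
    adjacent to the point reached by integrating the equations of motion
    *backwards* over one discrete interval from the bin center ``x(x_j)``
    (bilinear split over the four neighbouring bins), then each column is
    blurred with a Gaussian of ``smoothing_sigma`` bins and renormalized.
    With ``n_substeps=1`` the back-propagated point is exactly
    ``x(x_j) - f(x(x_j), a(u_k)) * dt``; the sub-stepped default evaluates
    the same displacement constraint with the flow properly integrated over
    the interval, which keeps remote states from aliasing onto spurious
    predecessors at coarse ``dt``.  Back-propagated points leaving the grid
    are clipped to the boundary bins (counted in the log).  ``R_k`` is the
    renormalized transpose of ``B_k``.
    """
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be >= 0")
    coords = grid.all_coords()
    n = grid.n_states
    B: list[np.ndarray] = []
    R = np.empty((len(grid.control_values), n, n))
    n_clipped = 0
    for k, a in enumerate(grid.control_values):
        back = _propagate(coords, a, dynamics, n_substeps, -1.0)
        lo = np.array([grid.pos_range[0], grid.vel_range[0]])
        hi = np.array([grid.pos_range[1], grid.vel_range[1]])
        n_clipped += int(np.any((back < lo) | (back > hi), axis=1).sum())
        ips, ivs, w = _bilinear_masses(grid, back)
        # mass[ip, iv, j]: previous-state distribution for current state j
        mass = np.zeros((grid.n_pos, grid.n_vel, n))
        cols = np.broadcast_to(np.arange(n)[:, None], ips.shape)
        np.add.at(mass, (ips.ravel(), ivs.ravel(), cols.ravel()), w.ravel())
        if smoothing_sigma > 0:
            mass = gaussian_filter(
                mass, sigma=(smoothing_sigma, smoothing_sigma, 0.0), mode="constant"
            )
        Bk = normalize_columns(mass.reshape(n, n))
        B.append(Bk)
        # sampling kernel: renormalized transpose of the pullback; states that
        # are nobody's predecessor get a forward-propagated (bilinear) column
        Rk = Bk.T.copy()
        empty = np.flatnonzero(Rk.sum(axis=0) <= 0)
        if empty.size:
            fwd = _propagate(coords[empty], a, dynamics, n_substeps, +1.0)
            ipf, ivf, wf = _bilinear_masses(grid, fwd)
            colf = np.broadcast_to(empty[:, None], ipf.shape)
            np.add.at(
                Rk, (ipf.ravel() * grid.n_vel + ivf.ravel(), colf.ravel()), wf.ravel()
            )
        R[k] = normalize_columns(Rk)
    if n_clipped:
        logger.info(
            "build_pullback: %d back-propagated points clipped to grid", n_clipped
        )
    return B, SamplingKernel(R)


def make_mountain_car_model(
    grid: GridSpec | None = None,
    dynamics: CarDynamics | None = None,
    goal: CarState = CarState(1.0, 0.0),
    smoothing_sigma: float = 1.0,
    T: int = 16,
    n_substeps: int = 40,
) -> tuple[DiscreteModel, SamplingKernel]:
    """Assemble the discrete generative model of the mountain-car task.

    Identity likelihood (states are observed directly), uniform prior over the
    five control levels, and a delta terminal prior on the bin containing the
    goal (default: parked at position 1 with zero velocity).
    """
    grid = grid or GridSpec()
    dynamics = dynamics or CarDynamics()
    B, R = build_pullback(dynamics, grid, smoothing_sigma, n_substeps=n_substeps)
    n = grid.n_states
    c = np.zeros(n)
    c[nearest_state_index(grid, goal)] = 1.0
    d = np.full(len(grid.control_values), 1.0 / len(grid.control_values))
    model = DiscreteModel(A=np.eye(n), B=B, c=c, d=d, T=T)
    return model, R
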