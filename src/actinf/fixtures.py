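"""Deterministic, seeded generators for every test input.

Nothing here is downloaded or read from disk: toy decision processes exercise
the discrete scheme against its exact oracles, and synthetic "glyph" images
stand in for photographic stimuli in the saccade simulator (an asymmetric
arrangement of Gaussian blobs and a bar, plus its inverted and rotated
variants, so the three hypotheses are genuinely discriminable at the fovea).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from actinf.discrete import (
    DiscreteModel,
    RewardSpec,
    SamplingKernel,
    normalize_columns,
)
from actinf.saccade import HypothesisSet, Image


@dataclass
class ToyMDPSpec:
    """Parameters of a random toy decision process.

    ``determinism`` is the probability mass placed on the designated successor
    state in each transition column (the rest is spread uniformly); the
    default is high so that posterior trajectories concentrate and mean-field
    marginals stay close to the exact smoother's.
    """

    n_states: int = 4
    n_actions: int = 3
    horizon: int = 3
    reward_sparsity: float = 0.25
    determinism: float = 0.9
    seed: int = 0


def make_toy_mdp(
    spec: ToyMDPSpec,
) -> tuple[DiscreteModel, SamplingKernel, RewardSpec, np.ndarray]:
    """Seeded toy model with consistent forward and pullback dynamics.

    Forward transitions ``Tr[a][x', x]`` place ``determinism`` mass on a
    random successor; the pullback ``B_a`` is the column-normalized transpose
    of ``Tr[a]`` (the stationary construction), the likelihood is the
    identity, the terminal prior is a delta on a random goal state and the
    control prior is uniform.  Rewards are drawn continuously so the optimal
    policy is unique with probability one.  Returns
    ``(model, sampling kernel, rewards, forward transitions)``.
    """
    rng = np.random.default_rng(spec.seed)
    nx, na = spec.n_states, spec.n_actions
    Tr = np.empty((na, nx, nx))
    for a in range(na):
        for x in range(nx):
            col = np.full(nx, (1.0 - spec.determinism) / nx)
            col[rng.integers(nx)] += spec.determinism
            Tr[a][:, x] = col
    B = [normalize_columns(Tr[a].T) for a in range(na)]
    c = np.zeros(nx)
    c[rng.integers(nx)] = 1.0
    d = np.full(na, 1.0 / na)
    model = DiscreteModel(A=np.eye(nx), B=B, c=c, d=d, T=spec.horizon)
    R = SamplingKernel(Tr.copy())
    r = rng.normal(size=nx) * (rng.random(nx) > spec.reward_sparsity)
    return model, R, RewardSpec(r), Tr


def make_diffuse_mdp(
    n_states: int = 4,
    n_actions: int = 3,
    horizon: int = 3,
    spread: float = 0.5,
    seed: int = 0,
) -> tuple[DiscreteModel, SamplingKernel]:
    """Weakly coupled toy model: transition columns are a uniform base plus a
    random perturbation of relative size ``spread``, with a delta terminal
    prior and identity likelihood.

    In this regime the trajectory posterior is close to factorized, so the
    mean-field marginals agree with the exact smoother's to high accuracy —
    the regime in which the variational updates can be validated against
    enumeration without confounding from the mean-field approximation error
    itself (strongly coupled toys have genuinely multimodal posteriors that
    no factorized approximation can match marginal-by-marginal).
    """
    rng = np.random.default_rng(seed)
    nx, na = n_states, n_actions
    Tr = np.empty((na, nx, nx))
    B = []
    for a in range(na):
        Tr[a] = normalize_columns(np.ones((nx, nx)) / nx + spread * rng.random((nx, nx)))
        B.append(normalize_columns(Tr[a].T))
    c = np.zeros(nx)
    c[rng.integers(nx)] = 1.0
    d = np.full(na, 1.0 / na)
    model = DiscreteModel(A=np.eye(nx), B=B, c=c, d=d, T=horizon)
    return model, SamplingKernel(Tr)


def make_deterministic_mdp(
    n_states: int = 4, n_actions: int = 3, seed: int = 0
) -> tuple[np.ndarray, RewardSpec]:
    """Random MDP with strictly deterministic transitions and continuous
    rewards (unique optimal policy almost surely).  Returns ``(Tr, rewards)``
    with ``Tr[a][x', x]`` one-hot columns."""
    rng = np.random.default_rng(seed)
    Tr = np.zeros((n_actions, n_states, n_states))
    for a in range(n_actions):
        for x in range(n_states):
            Tr[a][rng.integers(n_states), x] = 1.0
    return Tr, RewardSpec(rng.normal(size=n_states))


# ---------------------------------------------------------------------------
# Glyph imagery
# ---------------------------------------------------------------------------


@dataclass
class GlyphSpec:
    """Synthetic hypothesis-image generator parameters."""

    image_size: int = 128
    n_blobs: int = 4
    blob_sigma: float = 0.08  # in half-width units
    seed: int = 0


def _render_glyph(spec: GlyphSpec) -> np.ndarray:
    """Base glyph: asymmetric Gaussian blobs plus one bright bar, in [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    ax = np.linspace(-1.0, 1.0, n)
    X, Y = np.meshgrid(ax, ax[::-1])  # x rightward, y upward
    img = np.zeros((n, n))
    # blobs confined to an off-center annular region to break symmetry
    for _ in range(spec.n_blobs):
        cx = rng.uniform(-0.55, 0.55)
        cy = rng.uniform(-0.55, 0.55)
        amp = rng.uniform(0.6, 1.0)
        sig = spec.blob_sigma * rng.uniform(0.8, 1.6)
        img += amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sig**2))
    # one horizontal bar in the upper half (soft profile: razor edges make
    # the gaze-belief dynamics needlessly stiff)
    bar_y = rng.uniform(0.2, 0.5)
    img += 0.9 * np.exp(-((Y - bar_y) ** 2) / (2 * 0.06**2)) * np.exp(
        -np.clip(np.abs(X) - 0.45, 0, None) ** 2 / (2 * 0.08**2)
    )
    img /= max(img.max(), 1e-12)
    return img


def make_glyph_hypotheses(
    spec: GlyphSpec | None = None, noise_sigma: float = 0.0
) -> tuple[HypothesisSet, list[Image]]:
    """Three orientation variants of one glyph plus matched test scenes.

    The hypotheses are the base glyph, its 180-degree flip and its 90-degree
    rotation (pixel permutations of each other).  Each test scene equals the
    corresponding hypothesis, with optional seeded Gaussian noise of standard
    deviation ``noise_sigma``.
    """
    spec = spec or GlyphSpec()
    base = _render_glyph(spec)
    upright = Image(base)
    inverted = Image(base[::-1, ::-1].copy())
    rotated = Image(np.rot90(base).copy())
    hyps = HypothesisSet([upright, inverted, rotated])
    rng = np.random.default_rng(spec.seed + 1)
    scenes = []
    for h in hyps.images:
        arr = h.values.copy()
        if noise_sigma > 0:
            arr = np.clip(arr + rng.normal(0, noise_sigma, arr.shape), 0.0, 1.0)
        scenes.append(Image(arr))
    return hyps, scenes
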