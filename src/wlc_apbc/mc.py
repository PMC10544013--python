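"""Monte Carlo sampling of the discrete worm-like chain.

Two ensembles:

* free chains — sampled *exactly* (no Markov chain): the joint angles of
  the discrete WLC are independent, each with density proportional to
  ``sin(theta) exp(-alpha theta^2)`` on [0, pi], and azimuths are
  uniform;
* APBC-constrained chains — the end-to-end vector is pinned to
  (0, 0, L_z), a holonomic constraint, and the constraint surface is
  explored by Metropolis crankshaft rotations plus global z-rotations,
  both of which preserve every segment length and the end-to-end vector
  exactly.

The target density of the constrained sampler is proportional to
``exp(-E)`` (E the bending energy, optionally including the periodic
seam joint) on the constraint surface; proposals are symmetric, so
detailed balance holds with the standard min(1, e^-dE) rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import ChainConformation, WLCParameters

__all__ = [
    "MCConfig",
    "MCTrace",
    "MCDiagnosticsError",
    "sample_free_chain",
    "sample_free_directions",
    "sample_bend_angles",
    "init_apbc_chain",
    "crankshaft_move",
    "run_apbc_mcmc",
]


class MCDiagnosticsError(RuntimeError):
    """Raised when a run shows no mixing (e.g. zero acceptance over burn-in)."""


@dataclass(frozen=True)
class MCConfig:
    """Sampler bookkeeping: sweep counts, thinning, seed, move size.

    One sweep is N crankshaft proposals plus one global z-rotation.
    ``move_scale`` is the maximal crankshaft rotation angle in radians;
    with ``tune`` the scale is adjusted toward 30-50% acceptance during
    burn-in and frozen afterwards so detailed balance is untouched in
    the recorded portion.
    """

    n_sweeps: int = 20_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 0
    move_scale: float = np.pi / 2
    tune: bool = False
    include_seam: bool = True
    renorm_every: int = 1_000

    def __post_init__(self) -> None:
        if self.n_sweeps <= 0 or self.thin < 1 or self.burn_in < 0:
            raise ValueError("need n_sweeps > 0, thin >= 1, burn_in >= 0")
        if self.burn_in >= self.n_sweeps:
            raise ValueError("burn_in must be smaller than n_sweeps")
        if not 0 < self.move_scale <= np.pi:
            raise ValueError("move_scale must be in (0, pi]")


@dataclass
class MCTrace:
    """Thinned samples with energies and acceptance bookkeeping."""

    positions: np.ndarray  # (n_samples, N+1, 3)
    energies: np.ndarray
    acceptance_rate: float
    params: WLCParameters
    config: MCConfig
    final_move_scale: float = np.nan

    def __post_init__(self) -> None:
        if self.positions.shape[0] != self.energies.shape[0]:
            raise ValueError("positions and energies length mismatch")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def samples(self) -> list[ChainConformation]:
        return [ChainConformation(beads=p, delta=self.params.delta) for p in self.positions]

    @property
    def constrained(self) -> bool:
        return self.params.lz is not None


def sample_bend_angles(alpha: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw bend angles from density ~ sin(t) exp(-alpha t^2) on [0, pi].

    Exact rejection sampling with two envelopes: for soft chains the
    sine density itself (theta = arccos(1-2u)), for stiff chains the
    Rayleigh density ~ t exp(-alpha t^2) with acceptance weight
    sin(t)/t <= 1, which stays efficient as alpha grows.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    out = np.empty(size)
    filled = 0
    use_rayleigh = alpha >= 1.0
    while filled < size:
        m = max(2 * (size - filled), 1024)
        if use_rayleigh:
            t = np.sqrt(-np.log(rng.random(m)) / alpha)
            t = t[t < np.pi]
            keep = rng.random(t.size) < np.sin(t) / t
        else:
            t = np.arccos(1.0 - 2.0 * rng.random(m))
            if alpha > 0:
                keep = rng.random(m) < np.exp(-alpha * t * t)
            else:
                keep = np.ones(m, dtype=bool)
        t = t[keep]
        k = min(t.size, size - filled)
        out[filled : filled + k] = t[:k]
        filled += k
    return out


def sample_free_directions(
    params: WLCParameters, count: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Exact segment-direction samples for ``count`` free chains.

    Returns a (count, N, 3) array of unit vectors; the first segment of
    every chain points along +z, each subsequent one is bent from its
    predecessor by an angle from the Boltzmann bend density at a uniform
    azimuth.
    """
    if params.lz is not None:
        raise ValueError("free-chain sampling requires params without lz; use run_apbc_mcmc")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_segments
    dirs = np.empty((count, n, 3))
    dirs[:, 0] = (0.0, 0.0, 1.0)
    if n == 1:
        return dirs
    theta = sample_bend_angles(params.alpha, count * (n - 1), rng).reshape(count, n - 1)
    phi = rng.random((count, n - 1)) * 2.0 * np.pi
    u = dirs[:, 0].copy()
    z_ref = np.array([0.0, 0.0, 1.0])
    x_ref = np.array([1.0, 0.0, 0.0])
    for i in range(n - 1):
        ref = np.where(np.abs(u[:, 2:3]) < 0.9, z_ref, x_ref)
        a = np.cross(u, ref)
        a /= np.linalg.norm(a, axis=1, keepdims=True)
        b = np.cross(u, a)
        st = np.sin(theta[:, i])[:, None]
        ct = np.cos(theta[:, i])[:, None]
        u = st * np.cos(phi[:, i])[:, None] * a + st * np.sin(phi[:, i])[:, None] * b + ct * u
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        dirs[:, i + 1] = u
    return dirs


def sample_free_chain(
    params: WLCParameters, count: int, seed: int | np.random.Generator
) -> list[ChainConformation]:
    """Exact i.i.d. free-chain conformations (see :func:`sample_free_directions`)."""
    dirs = sample_free_directions(params, count, seed)
    beads = np.zeros((count, params.n_segments + 1, 3))
    np.cumsum(params.delta * dirs, axis=1, out=beads[:, 1:])
    return [ChainConformation(beads=b, delta=params.delta) for b in beads]


def init_apbc_chain(params: WLCParameters) -> ChainConformation:
    """Planar zig-zag satisfying the APBC constraint exactly.

    Beads run from the origin to (0, 0, lz); every segment advances
    lz/N in z and alternates in +-x so all lengths are exactly delta.
    """
    if params.lz is None:
        raise ValueError("init_apbc_chain requires params with lz")
    n, d, lz = params.n_segments, params.delta, params.lz
    cz = lz / (n * d)
    sx = d * np.sqrt(1.0 - cz * cz)
    beads = np.zeros((n + 1, 3))
    beads[:, 2] = np.arange(n + 1) * d * cz
    beads[1::2, 0] = sx
    return ChainConformation(beads=beads, delta=d)


def crankshaft_move(
    chain: ChainConformation, i: int, j: int, angle: float
) -> tuple[ChainConformation, bool]:
    """Rotate beads strictly between i and j about the i-j axis.

    Segment lengths and the end-to-end vector are preserved exactly (it
    is a rigid rotation of an interior block about an axis through its
    anchors).  Returns ``(new_chain, applied)``; coincident pivot beads
    make the move a flagged no-op.
    """
    n = chain.n_segments
    if not 0 <= i < j <= n:
        raise ValueError(f"need 0 <= i < j <= N={n}, got ({i}, {j})")
    beads = chain.beads.copy()
    applied = bool(_kernels._rotate_block(beads, i, j, float(angle)))
    return ChainConformation(beads=beads, delta=chain.delta), applied


def run_apbc_mcmc(params: WLCParameters, mc: MCConfig) -> MCTrace:
    """Metropolis sampling of the end-to-end constrained (APBC) ensemble.

    Every retained frame satisfies the constraint to floating-point
    accuracy (moves preserve it exactly; periodic renormalisation kills
    rounding drift).  Seeded runs are bit-reproducible on a given
    backend.  At alpha = 0 the target is flat on the constraint surface
    and every proposal is accepted.
    """
    if params.lz is None:
        raise ValueError("run_apbc_mcmc requires params with lz (the APBC constraint)")
    start = init_apbc_chain(params)
    beads = start.beads.copy()
    frames, energies, rate, scale = _kernels.run_apbc_kernel(
        beads,
        float(params.alpha),
        float(params.delta),
        float(params.lz),
        int(mc.n_sweeps),
        int(mc.burn_in),
        int(mc.thin),
        float(mc.move_scale),
        bool(mc.include_seam),
        bool(mc.tune),
        int(mc.renorm_every),
        int(mc.seed),
    )
    if params.alpha > 0 and rate == 0.0:
        raise MCDiagnosticsError(
            "no crankshaft move was accepted after burn-in; "
            "reduce move_scale or enable tuning"
        )
    return MCTrace(
        positions=frames,
        energies=energies,
        acceptance_rate=float(rate),
        params=params,
        config=mc,
        final_move_scale=float(scale),
    )
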