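"""Synthetic trajectory generators.

These emulate the *statistical structure* of all-atom DNA trajectories
— orientation-correlation decay, base-pair spacing, an ion atmosphere
with a prescribed radial profile — not the molecular physics, so every
analysis operation is testable without MD output.  All generators are
pure functions of (spec, seed).

Geometry defaults mirror B-DNA bookkeeping: 10 bp per helical pitch
(36 degrees of twist per base pair), 3.375 A rise, a 200 x 200 A
transverse box, and bulk KCl concentrations in the 0.25-1 M range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dna import RISE_PER_BP, BasePairTrajectory, IonTrajectory, NUMBER_DENSITY_TO_MOLAR

__all__ = [
    "HelixFixtureSpec",
    "IonFixtureSpec",
    "make_helix_trajectory",
    "make_correlated_helix",
    "make_ion_trajectory",
    "make_h_curve",
]


@dataclass(frozen=True)
class HelixFixtureSpec:
    """Noisy straight-helix surrogate for an APBC DNA trajectory.

    Base-pair centres sit on the z-axis at spacing ``rise`` (wrapped
    into [0, L_z)); orientation vectors tilt independently from +z by a
    half-normal angle of scale ``orientation_noise`` at an azimuth tied
    to the helical twist.  For independent tilts the closed-form
    expectation is ``<h_i . h_{i+j}> = exp(-orientation_noise**2)`` for
    j != 0 (mod N), since E[cos t] = exp(-sigma^2 / 2).
    """

    n_bp: int = 100
    rise: float = RISE_PER_BP
    twist_per_bp: float = 36.0  # degrees; 10 bp per helical pitch
    orientation_noise: float = 0.0  # radians
    positional_noise: float = 0.0  # angstrom
    n_frames: int = 1
    seed: int = 0
    box_xy: float = 200.0

    def __post_init__(self) -> None:
        if self.n_bp < 10 or self.n_bp % 10:
            raise ValueError("n_bp must be a positive multiple of 10")
        if self.orientation_noise < 0 or self.positional_noise < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class IonFixtureSpec:
    """Ion atmosphere surrogate: bulk species with optional radial enhancement.

    ``concentrations`` maps species labels to bulk molarities (mol/L).
    ``enhanced_species`` gets the target radial density
    ``c(r) = c_bulk * (1 + amplitude * exp(-r / decay_length))`` around
    the z-axis, sampled exactly by thinning a uniform Poisson draw.
    """

    concentrations: dict = field(default_factory=lambda: {"K+": 1.0, "Cl-": 1.0})
    enhanced_species: str | None = None
    amplitude: float = 0.0
    decay_length: float = 10.0  # angstrom
    box: tuple = (200.0, 200.0, 33.75)
    dna_spacing: float = RISE_PER_BP
    n_frames: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be >= 0")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def make_helix_trajectory(spec: HelixFixtureSpec) -> BasePairTrajectory:
    """Generate the noisy-helix base-pair trajectory described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n, f = spec.n_bp, spec.n_frames
    lz = spec.n_bp * spec.rise
    z = (np.arange(n) * spec.rise) % lz
    centers = np.zeros((f, n, 3))
    centers[:, :, 2] = z
    if spec.positional_noise > 0:
        centers += rng.normal(0.0, spec.positional_noise, size=(f, n, 3))
        centers[:, :, 2] %= lz
    tilt = np.abs(rng.normal(0.0, spec.orientation_noise, size=(f, n))) if spec.orientation_noise > 0 else np.zeros((f, n))
    twist = np.deg2rad(spec.twist_per_bp) * np.arange(n)
    azim = twist[None, :] + rng.uniform(0.0, 2.0 * np.pi, size=(f, n))
    h = np.empty((f, n, 3))
    h[:, :, 0] = np.sin(tilt) * np.cos(azim)
    h[:, :, 1] = np.sin(tilt) * np.sin(azim)
    h[:, :, 2] = np.cos(tilt)
    return BasePairTrajectory(
        centers=centers, orientations=h, box=(spec.box_xy, spec.box_xy, lz)
    )


def make_correlated_helix(
    n_bp: int,
    a_p: float,
    rise: float = RISE_PER_BP,
    n_frames: int = 50,
    seed: int = 0,
    box_xy: float = 200.0,
    box_z: float | None = None,
) -> BasePairTrajectory:
    """Helix whose orientations decay as ``<h_i . h_{i+j}> = exp(-j rise / a_p)``.

    Orientations perform a random walk on the unit sphere with a fixed
    bend angle ``beta = arccos(exp(-rise / a_p))`` and uniform azimuth,
    so the j-step correlation is exactly ``cos(beta)**j`` by the
    independence of successive bends.  The walk is open (no seam
    closure); intended for <H>(d) analyses at separations well below
    the period.  Pass a ``box_z`` larger than the chain extent to keep
    minimum-image distances equal to true index separations.
    """
    if a_p <= 0:
        raise ValueError("a_p must be > 0")
    rng = np.random.default_rng(seed)
    cb = np.exp(-rise / a_p)
    beta = np.arccos(cb)
    lz = n_bp * rise if box_z is None else box_z
    centers = np.zeros((n_frames, n_bp, 3))
    centers[:, :, 2] = np.arange(n_bp) * rise
    h = np.empty((n_frames, n_bp, 3))
    for f in range(n_frames):
        u = np.array([0.0, 0.0, 1.0])
        h[f, 0] = u
        for i in range(1, n_bp):
            ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            a = np.cross(u, ref)
            a /= np.linalg.norm(a)
            b = np.cross(u, a)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            u = np.sin(beta) * (np.cos(phi) * a + np.sin(phi) * b) + cb * u
            u /= np.linalg.norm(u)
            h[f, i] = u
    return BasePairTrajectory(centers=centers, orientations=h, box=(box_xy, box_xy, lz))


def make_ion_trajectory(spec: IonFixtureSpec) -> IonTrajectory:
    """Generate the ion-atmosphere surrogate described by ``spec``.

    Uniform species are homogeneous Poisson draws at the bulk number
    density; the enhanced species is drawn by thinning a uniform draw at
    the peak density against the target radial profile, which
    reproduces ``c(r)`` exactly in law.  The DNA is represented as beads
    along the z-axis.  Charge neutrality is not enforced (the profile,
    not electrostatics, is the emulated feature).
    """
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.box
    volume = lx * ly * lz
    n_dna = max(2, int(round(lz / spec.dna_spacing)))
    dna = np.zeros((n_dna, 3))
    dna[:, 2] = np.arange(n_dna) * spec.dna_spacing
    ions: dict[str, list[np.ndarray]] = {sp: [] for sp in spec.concentrations}
    for _ in range(spec.n_frames):
        for sp, molar in spec.concentrations.items():
            dens = molar / NUMBER_DENSITY_TO_MOLAR  # ions per A^3
            amp = spec.amplitude if sp == spec.enhanced_species else 0.0
            peak = dens * (1.0 + amp)
            n_draw = rng.poisson(peak * volume)
            xyz = rng.uniform(0.0, 1.0, size=(n_draw, 3)) * np.array([lx, ly, lz])
            xyz[:, 0] -= lx / 2.0
            xyz[:, 1] -= ly / 2.0
            if amp > 0:
                r = np.hypot(xyz[:, 0], xyz[:, 1])
                keep = rng.random(n_draw) < (1.0 + amp * np.exp(-r / spec.decay_length)) / (1.0 + amp)
                xyz = xyz[keep]
            ions[sp].append(xyz)
    return IonTrajectory(ions=ions, dna_atoms=[dna] * spec.n_frames, box=spec.box)


def make_h_curve(
    a_p: float,
    d_min: float = 3.0,
    d_max: float = 100.0,
    step: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
):
    """Synthetic <H>(d) curve ``exp(-d/a_p)`` with multiplicative noise.

    Returns a list of (d, value) pairs on a uniform grid; ``noise`` is
    the relative standard deviation (e.g. 0.01 for 1%).
    """
    rng = np.random.default_rng(seed)
    d = np.arange(d_min, d_max + 0.5 * step, step)
    v = np.exp(-d / a_p)
    if noise > 0:
        v = v * (1.0 + rng.normal(0.0, noise, size=d.size))
    return list(zip(d.tolist(), v.tolist()))
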