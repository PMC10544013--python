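"""Discrete worm-like chain: parameters, conformations, geometry, bending energy.

The chain is a sequence of N inextensible segments of length ``delta``
joined at beads; bending is penalised by the dimensionless energy
``E = alpha * sum_i theta_i**2`` with ``theta_i`` the angle between
adjacent segments (energy in units of k_B*T).  Conformations are stored
as bead positions so that the same type serves both the free ensemble
and the end-to-end constrained (APBC) ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WLCParameters",
    "ChainConformation",
    "ChainValidationError",
    "segment_vectors",
    "joint_angles",
    "bending_energy",
    "chain_from_angles",
]

#: relative tolerance on |‖l_i‖ − δ| accepted by validation
SEGMENT_LENGTH_RTOL = 1e-9


class ChainValidationError(ValueError):
    """Raised when a conformation violates the fixed-segment-length model."""


@dataclass(frozen=True)
class WLCParameters:
    """Model parameters (alpha, N, delta) with an optional APBC box length.

    Parameters
    ----------
    alpha : float
        Dimensionless bending stiffness, >= 0.  Energy is measured in
        units of k_B*T, so alpha is the only energetic parameter.
    n_segments : int
        Number of segments N >= 2 (the chain has N+1 beads).
    delta : float
        Segment length, > 0, in an arbitrary length unit.
    lz : float, optional
        Periodic box length along z.  When present the end-to-end vector
        is pinned to (0, 0, lz); requires 0 < lz < N*delta (equality
        would make the chain rigid and the constrained ensemble
        degenerate).
    """

    alpha: float
    n_segments: int
    delta: float = 1.0
    lz: float | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.n_segments < 2:
            raise ValueError(f"n_segments must be >= 2, got {self.n_segments}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.lz is not None:
            if not 0 < self.lz < self.n_segments * self.delta:
                raise ValueError(
                    f"lz must satisfy 0 < lz < N*delta = "
                    f"{self.n_segments * self.delta}, got {self.lz}"
                )

    @property
    def contour_length(self) -> float:
        return self.n_segments * self.delta


@dataclass
class ChainConformation:
    """Bead positions of a discrete chain with fixed segment length.

    ``beads`` is an (N+1, 3) array; consecutive beads are ``delta``
    apart within :data:`SEGMENT_LENGTH_RTOL`.
    """

    beads: np.ndarray
    delta: float = 1.0

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float)
        if self.beads.ndim != 2 or self.beads.shape[1] != 3 or self.beads.shape[0] < 3:
            raise ChainValidationError(
                f"beads must be an (N+1, 3) array with N >= 2, got shape {self.beads.shape}"
            )

    @property
    def n_segments(self) -> int:
        return self.beads.shape[0] - 1

    @property
    def end_to_end(self) -> np.ndarray:
        return self.beads[-1] - self.beads[0]

    def validate(self) -> None:
        """Check all segment lengths against ``delta``."""
        lens = np.linalg.norm(np.diff(self.beads, axis=0), axis=1)
        bad = np.abs(lens - self.delta) > SEGMENT_LENGTH_RTOL * self.delta + 1e-300
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ChainValidationError(
                f"segment {i} has length {lens[i]!r}, expected delta={self.delta!r}"
            )


def segment_vectors(chain: ChainConformation, validate: bool = True) -> np.ndarray:
    """Return the N segment vectors ``l_i = beads[i] - beads[i-1]``.

    Their sum equals the end-to-end displacement by construction.
    """
    if validate:
        chain.validate()
    return np.diff(chain.beads, axis=0)


def _angles_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angles between row vectors via atan2(|u×v|, u·v).

    Numerically stable at theta = 0 and pi, where arccos of a rounded
    dot product loses precision; stiff chains concentrate near 0.
    """
    cross = np.cross(u, v)
    dot = np.einsum("ij,ij->i", u, v)
    return np.arctan2(np.linalg.norm(cross, axis=1), dot)


def joint_angles(chain: ChainConformation, validate: bool = True) -> np.ndarray:
    """Return the N-1 joint angles theta_i in [0, pi].

    ``theta_i`` is the angle between segments l_i and l_{i+1}; the
    straight chain gives all zeros, a fold-back gives pi.
    """
    segs = segment_vectors(chain, validate=validate)
    norms = np.linalg.norm(segs, axis=1)
    if np.any(norms == 0):
        raise ChainValidationError("degenerate zero-length segment")
    return _angles_between(segs[:-1], segs[1:])


def seam_angle(chain: ChainConformation, validate: bool = False) -> float:
    """Angle between the last segment and the periodic image of the first.

    Under APBC the chain continues across the z-seam as segment 1
    translated by (0, 0, lz), so the seam joint is simply the angle
    between l_N and l_1.
    """
    segs = segment_vectors(chain, validate=validate)
    return float(_angles_between(segs[-1:], segs[:1])[0])


def bending_energy(
    chain: ChainConformation,
    params: WLCParameters,
    include_seam: bool = False,
    validate: bool = True,
) -> float:
    """Bending energy ``alpha * sum theta_i**2`` (dimensionless, k_B*T units).

    With ``include_seam`` the joint between segment N and the periodic
    image of segment 1 is added, which is the per-period energy of the
    infinite APBC chain.  Zero iff the chain is straight or alpha = 0.
    """
    th = joint_angles(chain, validate=validate)
    e = float(np.sum(th**2))
    if include_seam:
        e += seam_angle(chain) ** 2
    return params.alpha * e


def chain_from_angles(
    polar: np.ndarray,
    azimuth: np.ndarray,
    delta: float = 1.0,
    origin: np.ndarray | None = None,
) -> ChainConformation:
    """Build a conformation from N-1 bend angles and azimuths.

    The first segment points along +z; segment i+1 is obtained from
    segment i by bending through ``polar[i]`` at azimuth ``azimuth[i]``
    in the local frame of segment i.  Round-trips with
    :func:`joint_angles` (the azimuths are gauge, the polars are not).
    """
    polar = np.atleast_1d(np.asarray(polar, dtype=float))
    azimuth = np.atleast_1d(np.asarray(azimuth, dtype=float))
    if polar.shape != azimuth.shape:
        raise ValueError("polar and azimuth must have the same shape")
    n_seg = polar.size + 1
    dirs = np.empty((n_seg, 3))
    dirs[0] = (0.0, 0.0, 1.0)
    u = dirs[0]
    for i in range(polar.size):
        dirs[i + 1] = _bend(u, polar[i], azimuth[i])
        u = dirs[i + 1]
    beads = np.empty((n_seg + 1, 3))
    beads[0] = (0.0, 0.0, 0.0) if origin is None else np.asarray(origin, dtype=float)
    np.cumsum(delta * dirs, axis=0, out=beads[1:])
    beads[1:] += beads[0]
    return ChainConformation(beads=beads, delta=delta)


def _bend(u: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Unit vector at polar angle theta, azimuth phi from unit vector u."""
    # orthonormal frame (a, b, u); the azimuth origin is arbitrary gauge
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    a = np.cross(u, ref)
    a /= np.linalg.norm(a)
    b = np.cross(u, a)
    w = (
        np.sin(theta) * np.cos(phi) * a
        + np.sin(theta) * np.sin(phi) * b
        + np.cos(theta) * u
    )
    return w / np.linalg.norm(w)
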