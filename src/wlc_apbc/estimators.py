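"""Ensemble statistics: finite-j persistence lengths, the APBC midpoint
excursion, the local <cos theta> estimator and its inversion to a_orig.

Standard errors: independent free chains use the plain standard error
of the mean; MCMC traces use block averaging (blocks of 10 retained
samples by default) to absorb residual autocorrelation.  The a_orig
plug-in estimator propagates the <cos theta> error to first order
(delta method); it diverges as <cos theta> -> 1, which is exactly the
degeneracy of a fully stretched APBC chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .analytic import PersistenceResult
from .mc import MCTrace
from .model import ChainConformation

__all__ = [
    "EstimateWithError",
    "estimate_a_j",
    "estimate_midpoint_distance",
    "estimate_mean_cos",
    "estimate_a_orig_apbc",
    "block_standard_error",
]

#: default block length (in retained samples) for MCMC standard errors
BLOCK_LENGTH = 10


@dataclass(frozen=True)
class EstimateWithError:
    value: float
    std_error: float
    n_samples: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.value:.6g} +- {self.std_error:.2g} (n={self.n_samples})"


def block_standard_error(x: np.ndarray, block: int = BLOCK_LENGTH) -> tuple[float, float, int]:
    """Mean, blocked standard error and number of blocks of a series."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    n_blocks = x.size // block
    if n_blocks < 2:
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan, x.size
    bm = x[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    return float(bm.mean()), float(bm.std(ddof=1) / np.sqrt(n_blocks)), n_blocks


def _positions(chains) -> np.ndarray:
    """Stack chains/trace/array into an (n, N+1, 3) bead array."""
    if isinstance(chains, MCTrace):
        return chains.positions
    if isinstance(chains, np.ndarray):
        if chains.ndim != 3:
            raise ValueError("expected (n_chains, N+1, 3) array")
        return chains
    arrs = [c.beads if isinstance(c, ChainConformation) else np.asarray(c) for c in chains]
    if not arrs:
        raise ValueError("empty ensemble")
    return np.stack(arrs)


def estimate_a_j(chains, j: int, delta: float = 1.0) -> EstimateWithError:
    """Projection statistic a_j averaged over an ensemble.

    Per chain, the vector from the start to the end of the j-th segment
    is projected on the unit direction of the first segment:
    ``a_j = <(b_j - b_0) . l_1> / delta``.  Straight chains give j*delta
    and j = 1 gives delta identically.
    """
    pos = _positions(chains)
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 chains for a standard error")
    n = pos.shape[1] - 1
    if not 1 <= j <= n:
        raise ValueError(f"j must be in [1, N={n}], got {j}")
    first = pos[:, 1] - pos[:, 0]
    span = pos[:, j] - pos[:, 0]
    proj = np.einsum("ij,ij->i", span, first) / delta
    return EstimateWithError(
        value=float(proj.mean()),
        std_error=float(proj.std(ddof=1) / np.sqrt(proj.size)),
        n_samples=proj.size,
    )


def estimate_midpoint_distance(trace: MCTrace, params=None) -> EstimateWithError:
    """Mean transverse distance of the middle bead from the chain axis.

    The APBC chain has its ends pinned on the z-axis, so the axis
    through the endpoints is the z-axis itself and the statistic is the
    Euclidean norm of the x-y coordinates of bead N/2.  Requires a
    constrained trace and even N.
    """
    if not isinstance(trace, MCTrace) or not trace.constrained:
        raise ValueError("estimate_midpoint_distance requires a constrained (APBC) MCTrace")
    p = params if params is not None else trace.params
    n = p.n_segments
    if n % 2:
        raise ValueError("midpoint statistic is defined for even N")
    mid = trace.positions[:, n // 2, :2] - trace.positions[:, 0, :2]
    dist = np.linalg.norm(mid, axis=1)
    value, se, _ = block_standard_error(dist)
    return EstimateWithError(value=value, std_error=se, n_samples=dist.size)


def estimate_mean_cos(ensemble, wrap: bool = False) -> EstimateWithError:
    """Average cosine of the joint angles over all joints and samples.

    With ``wrap`` the joint between segment N and the periodic image of
    segment 1 (the APBC seam) is included, giving N joints per chain
    instead of N-1.  Straight chains give 1; free chains at alpha = 0
    give 0 in expectation.
    """
    pos = _positions(ensemble)
    segs = np.diff(pos, axis=1)
    u = segs / np.linalg.norm(segs, axis=2, keepdims=True)
    cos = np.einsum("nij,nij->ni", u[:, :-1], u[:, 1:])
    if wrap:
        seam = np.einsum("nj,nj->n", u[:, -1], u[:, 0])
        cos = np.concatenate([cos, seam[:, None]], axis=1)
    per_chain = cos.mean(axis=1)
    if isinstance(ensemble, MCTrace):
        value, se, _ = block_standard_error(per_chain)
    else:
        value = float(per_chain.mean())
        se = float(per_chain.std(ddof=1) / np.sqrt(per_chain.size)) if per_chain.size > 1 else np.nan
    return EstimateWithError(value=value, std_error=se, n_samples=per_chain.size)


def estimate_a_orig_apbc(mean_cos: EstimateWithError, delta: float = 1.0) -> tuple[PersistenceResult, EstimateWithError]:
    """Plug a measured <cos theta> into ``a_orig = delta / (1 - <cos theta>)``.

    This is the local route to the true persistence length from APBC
    simulations: adjacent-joint statistics are nearly unaffected by the
    constraint, while end-to-end statistics are pinned by it.  The
    standard error is propagated to first order,
    ``se_a = delta * se_c / (1 - c)^2``.  Raises when the estimate has
    reached 1 (straight chain; the relation diverges).
    """
    c = mean_cos.value
    if c >= 1.0:
        raise ValueError(
            "<cos theta> >= 1: the chain is straight and the persistence-length relation diverges"
        )
    a = delta / (1.0 - c)
    se = delta * mean_cos.std_error / (1.0 - c) ** 2
    result = PersistenceResult(a_value=a, method="from_cos_estimate")
    return result, EstimateWithError(value=a, std_error=se, n_samples=mean_cos.n_samples)
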