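"""Inner Monte Carlo loops, compiled with numba when available.

A crankshaft rotation about the axis through beads i and j rotates
segments i+1..j rigidly, so only the joint angles at beads i and j (and
the periodic seam joint when an end segment turns) change: the energy
update is O(1) per proposal regardless of chain length.

Randomness uses the numpy legacy MT19937 stream seeded inside the
kernel; bounded integers are derived from uniforms as ``int(u * n)`` so
compiled and fallback paths consume the same stream.  Seeded runs are
bit-reproducible within a backend; across backends the random streams
match but floating-point contraction (FMA) lets trajectories diverge.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=False)
def _joint_angle(u, v):
    """Angle between 3-vectors via atan2(|u x v|, u.v); stable near 0 and pi."""
    cx = u[1] * v[2] - u[2] * v[1]
    cy = u[2] * v[0] - u[0] * v[2]
    cz = u[0] * v[1] - u[1] * v[0]
    cross = np.sqrt(cx * cx + cy * cy + cz * cz)
    dot = u[0] * v[0] + u[1] * v[1] + u[2] * v[2]
    return np.arctan2(cross, dot)


@njit(cache=False)
def _angle_at(beads, k):
    """Joint angle at bead k (between segments k and k+1), 1 <= k <= N-1."""
    u = beads[k] - beads[k - 1]
    v = beads[k + 1] - beads[k]
    return _joint_angle(u, v)


@njit(cache=False)
def _seam_angle(beads):
    """Angle between the last segment and the periodic image of the first."""
    n = beads.shape[0] - 1
    u = beads[n] - beads[n - 1]
    v = beads[1] - beads[0]
    return _joint_angle(u, v)


@njit(cache=False)
def _rotate_block(beads, i, j, ang):
    """Rotate beads i+1..j-1 about the axis through beads i and j.

    Returns False (no-op) when the pivots coincide.
    """
    ax = beads[j] - beads[i]
    an = np.sqrt(ax[0] ** 2 + ax[1] ** 2 + ax[2] ** 2)
    if an < 1e-12:
        return False
    ax = ax / an
    ca = np.cos(ang)
    sa = np.sin(ang)
    p0 = beads[i]
    for k in range(i + 1, j):
        v = beads[k] - p0
        va = v[0] * ax[0] + v[1] * ax[1] + v[2] * ax[2]
        cx = ax[1] * v[2] - ax[2] * v[1]
        cy = ax[2] * v[0] - ax[0] * v[2]
        cz = ax[0] * v[1] - ax[1] * v[0]
        beads[k, 0] = p0[0] + v[0] * ca + cx * sa + ax[0] * va * (1.0 - ca)
        beads[k, 1] = p0[1] + v[1] * ca + cy * sa + ax[1] * va * (1.0 - ca)
        beads[k, 2] = p0[2] + v[2] * ca + cz * sa + ax[2] * va * (1.0 - ca)
    return True


@njit(cache=False)
def _local_energy(beads, i, j, alpha, include_seam):
    """Sum of squared angles at the joints a crankshaft (i, j) can change."""
    n = beads.shape[0] - 1
    e = 0.0
    if i >= 1:
        e += _angle_at(beads, i) ** 2
    if j <= n - 1:
        e += _angle_at(beads, j) ** 2
    if include_seam and (i == 0 or j == n):
        e += _seam_angle(beads) ** 2
    return alpha * e


@njit(cache=False)
def _total_energy(beads, alpha, include_seam):
    n = beads.shape[0] - 1
    e = 0.0
    for k in range(1, n):
        e += _angle_at(beads, k) ** 2
    if include_seam:
        e += _seam_angle(beads) ** 2
    return alpha * e


@njit(cache=False)
def _renormalize(beads, delta, lz):
    """Rebuild beads from unit segments to kill floating-point drift.

    The O(1e-15) endpoint residual left by renormalisation is spread as
    a linear ramp, perturbing each segment length by O(residual/N).
    """
    n = beads.shape[0] - 1
    prev = beads[0].copy()
    for k in range(1, n + 1):
        s = beads[k] - prev
        norm = np.sqrt(s[0] ** 2 + s[1] ** 2 + s[2] ** 2)
        prev = beads[k].copy()
        beads[k] = beads[k - 1] + s * (delta / norm)
    rx = beads[n, 0] - beads[0, 0]
    ry = beads[n, 1] - beads[0, 1]
    rz = beads[n, 2] - beads[0, 2] - lz
    for k in range(1, n + 1):
        f = k / n
        beads[k, 0] -= f * rx
        beads[k, 1] -= f * ry
        beads[k, 2] -= f * rz


@njit(cache=False)
def run_apbc_kernel(
    beads,
    alpha,
    delta,
    lz,
    n_sweeps,
    burn_in,
    thin,
    move_scale,
    include_seam,
    tune,
    renorm_every,
    seed,
):
    """Metropolis crankshaft sampling on the fixed end-to-end surface.

    One sweep = N crankshaft proposals + one global z-rotation (free,
    since all joint angles are invariant).  Returns retained bead
    frames, their energies, the post-burn-in acceptance rate and the
    move scale in force after tuning.
    """
    np.random.seed(seed)
    n = beads.shape[0] - 1
    n_keep = (n_sweeps - burn_in + thin - 1) // thin
    frames = np.empty((n_keep, n + 1, 3))
    energies = np.empty(n_keep)
    scale = move_scale
    acc = 0
    prop = 0
    tune_acc = 0
    tune_prop = 0
    kept = 0
    for sweep in range(n_sweeps):
        for _ in range(n):
            # i < j with at least one bead strictly between
            i = int(np.random.random() * (n - 1))  # 0..n-2
            j = i + 2 + int(np.random.random() * (n - i - 1))  # i+2..n
            ang = (2.0 * np.random.random() - 1.0) * scale
            e_old = _local_energy(beads, i, j, alpha, include_seam)
            saved = beads[i + 1 : j].copy()
            ok = _rotate_block(beads, i, j, ang)
            if not ok:
                continue
            e_new = _local_energy(beads, i, j, alpha, include_seam)
            d_e = e_new - e_old
            accept = d_e <= 0.0 or np.random.random() < np.exp(-d_e)
            if accept:
                if sweep >= burn_in:
                    acc += 1
                else:
                    tune_acc += 1
            else:
                beads[i + 1 : j] = saved
            if sweep >= burn_in:
                prop += 1
            else:
                tune_prop += 1
        # global rotation about the z-axis: constraint- and energy-preserving
        phi = 2.0 * np.pi * np.random.random()
        c = np.cos(phi)
        s = np.sin(phi)
        for k in range(n + 1):
            x = beads[k, 0]
            y = beads[k, 1]
            beads[k, 0] = c * x - s * y
            beads[k, 1] = s * x + c * y
        if tune and sweep < burn_in and (sweep + 1) % 200 == 0 and tune_prop > 0:
            rate = tune_acc / tune_prop
            if rate < 0.3:
                scale *= 0.8
            elif rate > 0.5:
                scale = min(np.pi, scale * 1.25)
            tune_acc = 0
            tune_prop = 0
        if renorm_every > 0 and (sweep + 1) % renorm_every == 0:
            _renormalize(beads, delta, lz)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            frames[kept] = beads
            energies[kept] = _total_energy(beads, alpha, include_seam)
            kept += 1
    rate = acc / prop if prop > 0 else 0.0
    return frames[:kept], energies[:kept], rate, scale
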