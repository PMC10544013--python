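"""Trajectory observables for DNA under asymmetric periodic boundaries.

Inputs are per-frame base-pair centres with unit orientation vectors
h_i (one per base pair) and, for the ion atmosphere, per-frame ion
coordinates with species labels.  All lengths are in angstroms.  The
box is periodic; the minimum-image convention is applied in z only
(period L_z), matching the APBC geometry in which the solute never
approaches the x/y faces.

B-DNA bookkeeping: the helical repeat is 10 base pairs and the box
rule fixes the rise at 3.375 A per base pair, so a chain of 10*n base
pairs fills exactly n helical pitches when L_z = 3.375 * n_bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .estimators import EstimateWithError

__all__ = [
    "RISE_PER_BP",
    "BasePairTrajectory",
    "IonTrajectory",
    "RadialProfile",
    "lz_for_bp",
    "cos_phi_profile",
    "bp_separation",
    "h_of_distance",
    "fit_persistence_exponential",
    "ion_radial_concentration",
    "FitDivergedError",
]

#: axial rise per base pair (angstrom) fixed by the box-length rule:
#: 100 bp corresponds to L_z = 337.5 A
RISE_PER_BP = 3.375

#: Avogadro constant (1/mol), for number-density -> molar conversion
_N_AVOGADRO = 6.02214076e23
#: (1/A^3) -> (mol/L): 1 L = 1e27 A^3
NUMBER_DENSITY_TO_MOLAR = 1e27 / _N_AVOGADRO


class FitDivergedError(RuntimeError):
    """The orientation-correlation curve shows no decay (a_p -> infinity)."""


@dataclass
class BasePairTrajectory:
    """Per-frame base-pair centres (A) and unit orientation vectors.

    ``centers`` and ``orientations`` are (n_frames, N, 3); ``box`` is
    (L_x, L_y, L_z); ``times`` are frame timestamps in ps.
    """

    centers: np.ndarray
    orientations: np.ndarray
    box: tuple[float, float, float]
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.centers.shape != self.orientations.shape or self.centers.ndim != 3:
            raise ValueError("centers and orientations must both be (n_frames, N, 3)")
        if self.box[2] <= 0:
            raise ValueError("L_z must be positive")
        norms = np.linalg.norm(self.orientations, axis=2)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("orientation vectors must be unit within 1e-6")
        if self.times is None:
            self.times = np.arange(self.centers.shape[0], dtype=float)

    @property
    def n_frames(self) -> int:
        return self.centers.shape[0]

    @property
    def n_bp(self) -> int:
        return self.centers.shape[1]


@dataclass
class IonTrajectory:
    """Per-frame ion coordinates with species labels plus DNA atoms.

    ``ions`` maps a species label (e.g. "K+", "Cl-") to a list of
    (n_ions, 3) arrays, one per frame; ``dna_atoms`` is a list of
    (n_atoms, 3) arrays, one per frame (may be an axis proxy).
    """

    ions: dict[str, list[np.ndarray]]
    dna_atoms: list[np.ndarray]
    box: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.ions = {
            sp: [np.asarray(f, dtype=float).reshape(-1, 3) for f in frames]
            for sp, frames in self.ions.items()
        }
        self.dna_atoms = [np.asarray(f, dtype=float).reshape(-1, 3) for f in self.dna_atoms]
        for sp, frames in self.ions.items():
            if not sp:
                raise ValueError("species labels must be nonempty")
            for f in frames:
                if not np.all(np.isfinite(f)):
                    raise ValueError(f"non-finite coordinates for species {sp!r}")

    @property
    def n_frames(self) -> int:
        return len(self.dna_atoms)


@dataclass
class RadialProfile:
    """Radial concentration on contiguous uniform bins.

    ``concentration`` is in ions/A^3 by default; :meth:`molar` converts
    to mol/L via 1e27 / N_A.
    """

    bin_edges: np.ndarray
    concentration: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.bin_edges.size != self.concentration.size + 1:
            raise ValueError("need len(bin_edges) == len(concentration) + 1")
        if np.any(self.concentration < -1e-300):
            raise ValueError("concentrations must be nonnegative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def molar(self) -> np.ndarray:
        return self.concentration * NUMBER_DENSITY_TO_MOLAR


def lz_for_bp(n_bp: int, scale: float = 1.0) -> float:
    """Box length rule: ``L_z = n_bp * 3.375 A`` for 10n base pairs.

    The APBC requires a whole number of helical pitches (10 bp each),
    so ``n_bp`` must be a multiple of 10; 100 bp gives 337.5 A.
    ``scale`` stretches or shrinks the box (e.g. 0.95 / 1.05).
    """
    if n_bp < 10 or n_bp % 10:
        raise ValueError(f"n_bp must be a positive multiple of 10, got {n_bp}")
    return n_bp * RISE_PER_BP * scale


def cos_phi_profile(traj: BasePairTrajectory, j: int) -> EstimateWithError:
    """<cos phi_j>: mean of h_i . h_{i+j} over all i (mod N) and frames.

    The periodic index wrap makes the profile symmetric,
    profile(j) = profile(N - j), and profile(N) = 1 identically (a base
    pair versus its own periodic image).  The mean over i is taken per
    frame first; the standard error is over frames.
    """
    n = traj.n_bp
    if not 1 <= j <= n:
        raise ValueError(f"j must be in [1, N={n}], got {j}")
    h = traj.orientations
    dots = np.einsum("fik,fik->fi", h, np.roll(h, -j, axis=1))
    per_frame = dots.mean(axis=1)
    se = per_frame.std(ddof=1) / np.sqrt(per_frame.size) if per_frame.size > 1 else 0.0
    return EstimateWithError(value=float(per_frame.mean()), std_error=float(se), n_samples=per_frame.size)


def _min_image_z(d: np.ndarray, lz: float) -> np.ndarray:
    d = d.copy()
    d[..., 2] -= lz * np.round(d[..., 2] / lz)
    return d


def bp_separation(traj: BasePairTrajectory) -> EstimateWithError:
    """Mean distance between consecutive base-pair centres.

    Includes the wrap pair (N, 1) through the minimum-image convention
    in z, so a uniform helix of rise r gives exactly r.
    """
    if traj.n_bp < 2:
        raise ValueError("need at least 2 base pairs")
    c = traj.centers
    d = _min_image_z(np.roll(c, -1, axis=1) - c, traj.box[2])
    dist = np.linalg.norm(d, axis=2)
    per_frame = dist.mean(axis=1)
    se = per_frame.std(ddof=1) / np.sqrt(per_frame.size) if per_frame.size > 1 else 0.0
    return EstimateWithError(value=float(per_frame.mean()), std_error=float(se), n_samples=per_frame.size)


def h_of_distance(traj: BasePairTrajectory, bin_width: float = 1.0, max_distance: float | None = None):
    """<H>(d): orientation dot products binned by spatial separation.

    All unordered pairs (i, j), i < j, in every frame contribute
    h_i . h_j to the bin of their centre-to-centre distance (minimum
    image in z).  Empty bins are omitted.  Returns a list of
    ``(distance, mean, count)`` tuples with ``distance`` the bin centre.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    c = traj.centers
    h = traj.orientations
    n = traj.n_bp
    iu, ju = np.triu_indices(n, k=1)
    dvec = _min_image_z(c[:, ju] - c[:, iu], traj.box[2])
    dist = np.linalg.norm(dvec, axis=2).ravel()
    dots = np.einsum("fik,fik->fi", h[:, iu], h[:, ju]).ravel()
    if max_distance is not None:
        keep = dist <= max_distance
        dist, dots = dist[keep], dots[keep]
    idx = np.floor(dist / bin_width).astype(int)
    order = np.argsort(idx, kind="stable")
    idx, dots = idx[order], dots[order]
    out = []
    for b, start, count in zip(*_run_lengths(idx)):
        out.append(((b + 0.5) * bin_width, float(dots[start : start + count].mean()), int(count)))
    return out


def _run_lengths(sorted_idx: np.ndarray):
    vals, starts, counts = np.unique(sorted_idx, return_index=True, return_counts=True)
    return vals, starts, counts


def fit_persistence_exponential(
    curve, d_min: float = 3.0, d_max: float = 100.0
) -> float:
    """Fit ``f(d) = exp(-d / a_p)`` to an orientation-correlation curve.

    ``curve`` is a sequence of (d, value[, count]) pairs; only points
    with ``d_min <= d <= d_max`` (defaults 3 and 100 A) enter the
    unweighted nonlinear least-squares fit.  The start value comes from
    a log-linear regression.  Returns a_p in angstroms (divide by 10
    for nm).  Scale-consistent: scaling all d by s scales a_p by s.
    """
    arr = np.asarray([(p[0], p[1]) for p in curve], dtype=float)
    sel = (arr[:, 0] >= d_min) & (arr[:, 0] <= d_max)
    d, v = arr[sel, 0], arr[sel, 1]
    if d.size < 3:
        raise ValueError(f"need >= 3 points in [{d_min}, {d_max}], got {d.size}")
    if np.any(v <= 0):
        raise ValueError("nonpositive correlation values in the fit range; exp(-d/a_p) cannot attain them")
    if np.any(v > 1.0 + 1e-9) and np.all(v >= 1.0):
        raise FitDivergedError("correlation does not decay; a_p is unbounded")
    # log-linear start: log v = -d/a
    slope = np.polyfit(d, np.log(v), 1)[0]
    if slope >= -1e-12:
        raise FitDivergedError("correlation does not decay over the fit range; a_p -> infinity")
    a0 = -1.0 / slope
    popt, _ = optimize.curve_fit(lambda x, a: np.exp(-x / a), d, v, p0=[a0], maxfev=10_000)
    return float(popt[0])


def ion_radial_concentration(
    traj: IonTrajectory,
    species: str,
    dr: float = 1.0,
    mode: str = "nearest_atom",
    r_max: float | None = None,
) -> RadialProfile:
    """Radial ion concentration around the DNA in cylindrical-shell units.

    Per frame, each ion's distance from the DNA is either the distance
    to the nearest DNA atom (``mode="nearest_atom"``, the histogram
    convention) or the distance to the z-axis (``mode="axis"``).  The
    frame-averaged count in (r, r + dr) is divided by the straight-
    cylinder shell volume ``V(r, dr) = 2 pi r dr L_z`` evaluated at the
    bin centre, approximating the DNA as a straight line along z.
    """
    if species not in traj.ions:
        raise KeyError(f"species {species!r} not in trajectory (have {sorted(traj.ions)})")
    if dr <= 0:
        raise ValueError("dr must be positive")
    if mode not in ("nearest_atom", "axis"):
        raise ValueError(f"mode must be 'nearest_atom' or 'axis', got {mode!r}")
    lz = traj.box[2]
    if r_max is None:
        r_max = 0.5 * float(np.hypot(traj.box[0], traj.box[1]))
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(edges.size - 1)
    n_frames = traj.n_frames
    for f in range(n_frames):
        ions = traj.ions[species][f]
        if mode == "axis":
            r = np.hypot(ions[:, 0], ions[:, 1])
        else:
            atoms = traj.dna_atoms[f]
            if atoms.size == 0:
                raise ValueError(f"frame {f} has no DNA atoms")
            diff = ions[:, None, :] - atoms[None, :, :]
            diff = _min_image_z(diff, lz)
            r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff)).min(axis=1)
        counts += np.histogram(r, bins=edges)[0]
    counts /= n_frames
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_volume = 2.0 * np.pi * centers * dr * lz
    return RadialProfile(bin_edges=edges, concentration=counts / shell_volume, species=species)
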