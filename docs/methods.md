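# Methods

## Model

The chain is the discrete worm-like chain: N+1 beads joined by N segments
of fixed length δ, with dimensionless bending energy E = α Σ θ_i² over the
N−1 interior joints (θ_i ∈ [0, π] between segments i and i+1; energy in
units of k_BT). There is no twist and no stretching term. Conformations
are stored as bead positions, not angles, so the same container serves the
free and the constrained ensemble; angle-based construction
(`chain_from_angles`) is a convenience, not the canonical state. Segment
lengths are validated to a relative tolerance of 1e−9; all Monte Carlo
moves are rigid rotations, which preserve lengths exactly up to rounding.

Joint angles are computed as atan2(|u×v|, u·v) rather than arccos of the
normalised dot product: stiff chains concentrate near θ = 0, where the
inverse cosine loses half the available precision.

## Free-chain theory

For the free chain the joints are independent with angular density
∝ sin θ · e^{−αθ²}. Everything follows from the single moment
⟨cos θ⟩(α):

- ⟨cos θ⟩ is evaluated by adaptive quadrature on [0, π] with absolute and
  relative tolerance 1e−12. For α > 500 the integrand underflows and the
  code switches to the asymptotic series, which is already accurate to
  ~1e−9 there.
- The large-α series is ⟨cos θ⟩ = 1 − 1/(2α) + 1/(6α²) + O(α⁻³), obtained
  by term-by-term Gaussian integration of sin θ and sin θ cos θ on [0, ∞)
  (the [π, ∞) truncation error is e^{−απ²}, negligible). Measured against
  quadrature: 5.2% relative error at α = 1, 0.57% at α = 2, monotonically
  decreasing — matching the claimed validity "about 5% for α > 1, below 1%
  for α > 2".
- a_j = δ(1 − c^j)/(1 − c) with c = ⟨cos θ⟩ (geometric sum of projections),
  and a_orig = δ/(1 − c). The two asymptotes are 2δα and 2δα + 2δ/3; the
  two-term form tracks the exact curve once a_orig > 2δ, i.e. α > 0.62
  (numerically a_orig(0.62) = 2.007 δ).
- Finite-j inversion: for stiff chains c^j → e^{−jδ/a_orig}, giving
  a_j = a_orig(1 − e^{−jδ/a_orig}). `a_orig_from_aj` inverts this in closed
  form via the Lambert W function: with b = a_j/(jδ) and
  u = 1/b + W₀(−(1/b)e^{−1/b}), a_orig = jδ/u. The relation is a
  large-stiffness approximation; round-trip error against the exact
  formulas is ~1.5% at (α = 5, j = 25) and vanishes as a_j saturates.
  For α ≤ 1 the result is returned flagged out-of-validity rather than
  refused.

Free chains are sampled *exactly*: each bend angle is drawn by rejection —
against the sine envelope (θ = arccos(1 − 2u)) for α < 1, against the
Rayleigh envelope θ² ~ Exp(α) with acceptance weight sin θ/θ for α ≥ 1,
which stays efficient for arbitrarily stiff chains — and rotated into the
frame of the previous segment at a uniform azimuth.

## APBC-constrained ensemble

The asymmetric periodic box imposes Σ **l**_i = (0, 0, L_z) with
0 < L_z < Nδ. The target density is ∝ e^{−E} on that constraint surface.
By default E includes the seam joint between segment N and the periodic
image of segment 1, since one period of the infinite chain has N joints;
`include_seam=False` reproduces the open-chain convention, and the
estimator-side `wrap` flag exposes the same choice for ⟨cos θ⟩ averages.
The two conventions agree to well within sampling error for the compact
boxes of interest.

Sampling uses Metropolis crankshaft moves: pivot beads i < j are drawn
uniformly (j ≥ i + 2), and beads strictly between them rotate about the
i–j axis by an angle uniform on [−s, s]. A crankshaft rotates segments
i+1..j rigidly, so only the joint angles at the pivots (plus the seam when
an end segment turns) change — the energy update is O(1) per proposal
regardless of N. One sweep is N crankshaft proposals plus one global
z-rotation (which changes no angle and keeps the azimuthal distribution
ergodic). Proposals are symmetric, acceptance is min(1, e^{−ΔE}), and at
α = 0 every proposal is accepted. The default move scale is π/2; optional
tuning during burn-in targets 30–50% acceptance and is frozen afterwards so
detailed balance holds in the recorded portion. Bead coordinates are
renormalised from unit segments every 10³ sweeps to kill rounding drift
(observed drift ≤ 1e−12 over full runs; the invariant asserted is 1e−8).
Randomness is the numpy legacy MT19937 stream seeded inside the kernel;
numba reproduces the same stream, and seeded runs are bit-reproducible
within a backend (compiled or pure-Python). Across backends the
trajectories eventually diverge at machine precision — compiled code may
contract multiply-adds — so reproducibility claims are per-backend.

Correctness of the sampler was established against an independent oracle:
free chains conditioned on |end-to-end| falling in a shrinking window
(rejection sampling; the bending energy is rotation-invariant, so
conditioning on the norm is conditioning on the vector up to an irrelevant
global rotation). At N = 4 and N = 8 the two routes agree within combined
Monte Carlo error.

## Midpoint excursion and its two theory curves

The statistic is the mean Euclidean norm of the x–y coordinates of bead
N/2 (the endpoints sit on the z-axis, so the axis through the endpoints is
the z-axis). It *increases with stiffness* at fixed L_z and decays to zero
as L_z → Nδ. Two closed-form curves bracket the behaviour:

- **Helix radius** (`midpoint_distance_theory`): the minimum-bending-energy
  conformation compatible with the constraint and the periodic continuation
  is the single-turn helix of pitch L_z, whose radius
  δ√(1 − (L_z/Nδ)²)/(2 sin(π/N)) ≈ (Nδ/2π)√(1 − (L_z/Nδ)²) is independent
  of the value of α (minimisers do not move when the energy is scaled).
  Stiff, strongly coiled chains (persistence length ≫ the slack per turn)
  sample near this radius: at N = 100, α = 5 the measured excursions are
  15.7 ± 0.5 vs 15.84 (L_z = 10) and 13.4 ± 0.5 vs 13.79 (L_z = 50).
  Toward full extension thermal fluctuations dominate the shrinking
  ground-state radius and the sampled value falls below the curve.
- **Entropic bridge** (`midpoint_distance_ideal`): for α = 0 the segments
  are an ideal fixed-step walk bridged to (0, 0, L_z). For large N the
  conditioned walk has per-step transverse variance δ²μ/k per component
  (μ = L_z/Nδ, k the inverse Langevin function of μ) and the midpoint of a
  bridge carries half the free variance, giving
  ⟨R⟩ = (δ/2)√(πL_z/(2kδ)). Measured α = 0 runs at N = 100 agree within
  1 SE at L_z ∈ {10, 50, 90}; the formula is a large-N asymptote with
  finite-N truncation at the ~2% level, which is why curve comparisons in
  the tests carry a small relative allowance on top of 3 SE.

## Persistence length from APBC runs

End-to-end statistics of the constrained chain are uninformative (the
periodic filament is effectively straight), so the estimator of choice is
local: average cos θ over all joints and samples, then plug into
a_orig = δ/(1 − ⟨cos θ⟩), with first-order (delta-method) error
propagation se_a = δ·se_c/(1 − c)² — documented as approximate. The
estimator diverges as ⟨cos θ⟩ → 1, which is exactly the L_z → Nδ
degeneracy. Standard errors for MCMC traces use block averaging (blocks of
10 retained samples) to absorb autocorrelation; independent free chains use
the plain standard error.

Characterisation at N = 100: for compact boxes (L_z ≤ 30 δ) the recovered
a_orig sits within ~1–2% of the exact value for α ∈ {1, 5, 10}; the offset
is a genuine finite-box systematic (the coiled chain bends slightly more
than a free one, lowering ⟨cos θ⟩), so the tests assert a 3.5% relative
tolerance rather than a pure statistical-consistency bound, which no
sufficiently long run could satisfy. For stretched boxes the bias turns
positive and grows rapidly (+24% at α = 5, L_z = 90), the signature of the
straight-chain divergence.

## DNA trajectory observables

Inputs are per-frame base-pair centres with unit orientation vectors h_i
(the package deliberately accepts precomputed h_i rather than inventing a
base-pair frame construction from atoms) and per-frame ion coordinates
with species labels; lengths in Å. Minimum image is applied in z only
(period L_z) — the APBC geometry keeps the solute away from the x/y faces.

- Box rule: L_z = 3.375 Å × n_bp, n_bp a multiple of 10 (one helical pitch
  per 10 bp); 100 bp → 337.5 Å. A scale factor supports the 95%/100%/105%
  stretched-box protocol.
- ⟨cos φ_j⟩ averages h_i·h_{i+j} over all i with periodic index wrap; the
  profile is exactly symmetric, profile(j) = profile(N−j), and
  profile(N) = 1 identically. Frame means are taken first and the standard
  error is over frames (i-averaging before time-averaging; the mean is
  order-independent, only the SE convention needed fixing).
- Base-pair separation averages the distance between consecutive centres,
  the wrap pair (N, 1) included via minimum image.
- ⟨H⟩(d) bins h_i·h_j over all unordered pairs by centre-to-centre
  distance; empty bins are omitted, not zero-filled.
- The persistence fit minimises unweighted least squares of the
  one-parameter model exp(−d/a_p) over 3 ≤ d ≤ 100 Å by default (nonlinear
  fit, log-linear start). Nonpositive values in range are an error (the
  model cannot attain them); a non-decaying curve raises a divergence
  error. The fit is exactly scale-consistent.
- Ion radial concentration: per-frame histogram of ion–DNA distances
  (nearest DNA atom, or distance to the z-axis), frame-averaged counts
  divided by the straight-cylinder shell volume 2πr Δr L_z with Δr = 1 Å
  by default and r the bin centre (the choice of r within the bin is
  second-order in Δr). Molar conversion is number density (Å⁻³) ×
  10²⁷/6.02214076×10²³; with bin-centre volumes, summing concentration ×
  shell volume returns the mean ion count exactly (axis mode).

## Synthetic data

The generators emulate statistical structure, not molecular physics:

- `make_helix_trajectory`: centres on the z-axis at the B-DNA rise,
  orientations tilted independently from +z by half-normal angles (scale
  σ) at twist-linked azimuths. Closed form: ⟨h_i·h_{i+j}⟩ = e^{−σ²} for
  j ≠ 0 (mod N), since E[cos t] = e^{−σ²/2} for a (half-)normal tilt.
- `make_correlated_helix`: orientations perform a fixed-bend random walk on
  the sphere, giving ⟨h_i·h_{i+j}⟩ = exp(−j·rise/a_p) exactly in
  expectation — the fixture for ⟨H⟩(d) recovery. The walk is open, so a
  wrapped profile mixes in c^{N−j} image terms; tests either account for
  the mixture or enlarge the box so minimum image is inert.
- `make_ion_trajectory`: homogeneous Poisson ions at the bulk molarity;
  the enhanced species is thinned against
  c(r) = c₀(1 + A e^{−r/λ}), reproducing the target radial law exactly.
  DNA is a bead string on the axis. Charge neutrality is not enforced.

What passing tests therefore show: the estimators recover known
statistical structure (decay constants, bulk densities, wrap symmetries)
from data shaped like MD output. What they do not show: anything about
force fields, sequence dependence, or real ion–DNA energetics — sequence
effects and the published MD persistence lengths (~50–78 nm) require
all-atom simulation and are out of scope here.

## Problem sizes and numerical choices

Test and acceptance runs use N = 100 chains, 6–12 ×10³ sweeps (burn-in
1.5–5 ×10³, thinning 4–10), 10⁴ free chains, and 20-frame ion boxes —
sizes at which every sampled-vs-theory comparison resolves its claim at
the stated tolerance while a full suite completes in about a minute on one
core. Degenerate inputs fail loudly: overstretched boxes (L_z ≥ Nδ),
zero-length segments, ⟨cos θ⟩ ≥ 1 in the plug-in estimator, non-decaying
correlation curves, unknown ion species. Crankshaft proposals with
coincident pivots are flagged no-ops, not errors, inside the sampler.

## Known limitations

- No twist degree of freedom, no stretching energy, no force–extension
  protocol.
- The midpoint theory curves are regime asymptotes (stiff-coil helix,
  flexible large-N bridge); neither interpolates the crossover at
  intermediate stiffness, where only the sampler answers.
- The Lambert-W finite-j inversion inherits the stiff-chain approximation;
  for α ≲ 1 use the exact formulas directly.
- First-order error propagation through δ/(1 − c) understates uncertainty
  as c → 1.
- The ion shell normalisation treats the DNA as a straight cylinder; for
  strongly bent molecules the nearest-atom histogram remains valid but the
  volume factor does not.
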