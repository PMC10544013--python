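import numpy as np
import pytest

from wlc_apbc import (
    BasePairTrajectory,
    FitDivergedError,
    HelixFixtureSpec,
    IonFixtureSpec,
    bp_separation,
    cos_phi_profile,
    fit_persistence_exponential,
    h_of_distance,
    ion_radial_concentration,
    lz_for_bp,
    make_correlated_helix,
    make_h_curve,
    make_helix_trajectory,
    make_ion_trajectory,
)
from wlc_apbc.dna import NUMBER_DENSITY_TO_MOLAR, RISE_PER_BP


class TestBoxRule:
    def test_hundred_bp_value(self):
        assert lz_for_bp(100) == pytest.approx(337.5)

    def test_proportionality(self):
        assert lz_for_bp(10) == pytest.approx(33.75)
        assert lz_for_bp(50) == pytest.approx(5 * 33.75)

    def test_stretch_and_shrink_factors(self):
        assert lz_for_bp(100, scale=0.95) == pytest.approx(0.95 * 337.5)
        assert lz_for_bp(100, scale=1.05) == pytest.approx(1.05 * 337.5)

    @pytest.mark.parametrize("n", [0, 5, 12, 101])
    def test_non_multiples_rejected(self, n):
        with pytest.raises(ValueError):
            lz_for_bp(n)


class TestCosPhiProfile:
    def test_identical_orientations_give_one(self):
        traj = make_helix_trajectory(HelixFixtureSpec(n_bp=20, n_frames=3))
        for j in [1, 7, 20]:
            assert cos_phi_profile(traj, j).value == pytest.approx(1.0, abs=1e-12)

    def test_periodic_image_identity_at_j_equals_n(self):
        traj = make_helix_trajectory(
            HelixFixtureSpec(n_bp=10, n_frames=4, orientation_noise=0.3, seed=3)
        )
        assert cos_phi_profile(traj, 10).value == pytest.approx(1.0, abs=1e-12)

    def test_wrap_symmetry_is_exact(self):
        traj = make_helix_trajectory(
            HelixFixtureSpec(n_bp=30, n_frames=5, orientation_noise=0.4, seed=4)
        )
        for j in [1, 5, 12]:
            a = cos_phi_profile(traj, j).value
            b = cos_phi_profile(traj, 30 - j).value
            assert a == pytest.approx(b, abs=1e-12)

    def test_constructed_correlation_recovered(self):
        # random spherical walk with fixed bend: <h_i.h_{i+j}> = c^j
        a_p = 200.0
        traj = make_correlated_helix(100, a_p, n_frames=120, seed=5, box_z=1e6)
        c = np.exp(-RISE_PER_BP / a_p)
        for j in [1, 3]:
            est = cos_phi_profile(traj, j)
            # wrap pairs contribute c^(N-j) ~ 0; mixture expectation:
            expected = ((100 - j) * c**j + j * c ** (100 - j)) / 100
            assert abs(est.value - expected) < 3 * est.std_error

    def test_out_of_range_j(self):
        traj = make_helix_trajectory(HelixFixtureSpec(n_bp=10))
        for j in [0, 11]:
            with pytest.raises(ValueError):
                cos_phi_profile(traj, j)


class TestBpSeparation:
    def test_uniform_helix_gives_rise_exactly(self):
        traj = make_helix_trajectory(HelixFixtureSpec(n_bp=50, n_frames=2))
        assert bp_separation(traj).value == pytest.approx(RISE_PER_BP, abs=1e-9)

    def test_two_frame_hand_arithmetic(self):
        # two bp, two frames; wrap pair counted by minimum image in z
        lz = 10.0
        c1 = [[0, 0, 0], [0, 0, 4.0]]
        c2 = [[0, 0, 0], [3.0, 0, 4.0]]
        h = [[0, 0, 1.0], [0, 0, 1.0]]
        traj = BasePairTrajectory(
            centers=np.array([c1, c2]), orientations=np.array([h, h]), box=(50, 50, lz)
        )
        # frame 1: d(1,2) = 4; wrap pair dz = -4 (minimum image) -> 4 => mean 4
        # frame 2: d(1,2) = sqrt(9+16) = 5; wrap dz = -4 -> 5 => mean 5
        assert bp_separation(traj).value == pytest.approx(4.5, abs=1e-12)

    def test_stretched_box_increases_separation(self):
        base = make_helix_trajectory(HelixFixtureSpec(n_bp=50, n_frames=2))
        stretched = BasePairTrajectory(
            centers=base.centers * np.array([1.0, 1.0, 1.05]),
            orientations=base.orientations,
            box=(base.box[0], base.box[1], base.box[2] * 1.05),
        )
        assert bp_separation(stretched).value > bp_separation(base).value


class TestHOfDistance:
    def test_identical_orientations_give_unit_bins(self):
        traj = make_helix_trajectory(HelixFixtureSpec(n_bp=30, n_frames=2))
        curve = h_of_distance(traj, bin_width=2.0)
        assert curve  # nonempty
        for _, value, count in curve:
            assert value == pytest.approx(1.0, abs=1e-12)
            assert count > 0

    def test_constructed_decay_on_curve(self):
        a_p = 150.0
        traj = make_correlated_helix(80, a_p, n_frames=150, seed=6, box_z=1e6)
        curve = h_of_distance(traj, bin_width=RISE_PER_BP, max_distance=80.0)
        for d, v, n in curve:
            if d < 5:  # self-adjacent bin: near 1 for a stiff walk
                assert v > 0.9
        fitted = fit_persistence_exponential(curve, d_min=3.0, d_max=80.0)
        assert fitted == pytest.approx(a_p, rel=0.1)

    def test_empty_bins_omitted(self):
        traj = make_helix_trajectory(HelixFixtureSpec(n_bp=20, n_frames=1))
        curve = h_of_distance(traj, bin_width=0.5)
        # centres are multiples of the rise: bins between them are absent
        distances = [d for d, _, _ in curve]
        assert len(distances) < (20 * RISE_PER_BP) / 0.5


class TestExponentialFit:
    def test_exact_curve_self_consistency(self):
        curve = make_h_curve(500.0)
        assert fit_persistence_exponential(curve) == pytest.approx(500.0, rel=1e-6)

    def test_scale_consistency(self):
        curve = make_h_curve(120.0, noise=0.01, seed=7)
        a1 = fit_persistence_exponential(curve, d_min=3, d_max=100)
        scaled = [(3 * d, v) for d, v in curve]
        a3 = fit_persistence_exponential(scaled, d_min=9, d_max=300)
        assert a3 == pytest.approx(3 * a1, rel=1e-9)

    def test_constant_curve_diverges(self):
        curve = [(d, 1.0) for d in range(3, 101)]
        with pytest.raises(FitDivergedError):
            fit_persistence_exponential(curve)

    def test_nonpositive_values_rejected(self):
        curve = [(3.0, 0.5), (4.0, -0.1), (5.0, 0.4), (6.0, 0.3)]
        with pytest.raises(ValueError):
            fit_persistence_exponential(curve)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_persistence_exponential([(5.0, 0.9), (6.0, 0.8)])


class TestIonRadialConcentration:
    def test_uniform_ions_flat_at_bulk(self):
        spec = IonFixtureSpec(
            concentrations={"K+": 1.0, "Cl-": 1.0}, n_frames=20, seed=8
        )
        traj = make_ion_trajectory(spec)
        prof = ion_radial_concentration(traj, "K+", dr=8.0, mode="axis", r_max=80.0)
        molar = prof.molar()
        assert np.mean(molar) == pytest.approx(1.0, rel=0.03)
        # per-bin Poisson tolerance: 5 sigma on the expected shell count
        lz = traj.box[2]
        dens = 1.0 / NUMBER_DENSITY_TO_MOLAR
        expected = 2 * np.pi * prof.bin_centers * 8.0 * lz * dens * spec.n_frames
        assert np.all(np.abs(molar - 1.0) < 5.0 / np.sqrt(expected))

    def test_count_conservation_identity(self):
        spec = IonFixtureSpec(concentrations={"K+": 0.5}, n_frames=3, seed=9)
        traj = make_ion_trajectory(spec)
        lx, ly, lz = traj.box
        r_max = np.hypot(lx, ly)  # covers every ion in the box corners
        prof = ion_radial_concentration(traj, "K+", dr=1.0, mode="axis", r_max=r_max)
        vols = 2 * np.pi * prof.bin_centers * 1.0 * lz
        total = np.sum(prof.concentration * vols)
        mean_count = np.mean([f.shape[0] for f in traj.ions["K+"]])
        assert total == pytest.approx(mean_count, rel=1e-9)

    def test_enhanced_species_decays_from_axis(self):
        spec = IonFixtureSpec(
            concentrations={"K+": 1.0, "Cl-": 1.0},
            enhanced_species="K+",
            amplitude=4.0,
            decay_length=15.0,
            n_frames=8,
            seed=10,
        )
        traj = make_ion_trajectory(spec)
        k = ion_radial_concentration(traj, "K+", dr=10.0, mode="axis", r_max=90.0).molar()
        cl = ion_radial_concentration(traj, "Cl-", dr=10.0, mode="axis", r_max=90.0).molar()
        assert k[0] > k[-1]  # enhancement decays with r
        assert k[0] > cl[0] * 2  # cation excess near the axis
        assert k[-1] == pytest.approx(cl[-1], rel=0.2)  # bulk values agree

    def test_nearest_atom_mode_close_to_axis_mode_for_axial_dna(self):
        spec = IonFixtureSpec(concentrations={"K+": 1.0}, n_frames=3, seed=11)
        traj = make_ion_trajectory(spec)
        near = ion_radial_concentration(traj, "K+", dr=10.0, mode="nearest_atom", r_max=60.0)
        axis = ion_radial_concentration(traj, "K+", dr=10.0, mode="axis", r_max=60.0)
        # DNA beads sit on the axis every 3.375 A: distances differ by < one spacing
        assert np.allclose(near.molar()[2:], axis.molar()[2:], rtol=0.25)

    def test_unknown_species_and_bad_dr(self):
        traj = make_ion_trajectory(IonFixtureSpec(n_frames=1, seed=12))
        with pytest.raises(KeyError):
            ion_radial_concentration(traj, "Na+")
        with pytest.raises(ValueError):
            ion_radial_concentration(traj, "K+", dr=0.0)

    def test_zero_concentration_species_gives_zero_profile(self):
        spec = IonFixtureSpec(concentrations={"K+": 1.0, "Cl-": 0.0}, n_frames=2, seed=13)
        traj = make_ion_trajectory(spec)
        prof = ion_radial_concentration(traj, "Cl-", dr=5.0, mode="axis", r_max=50.0)
        assert np.all(prof.concentration == 0.0)
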