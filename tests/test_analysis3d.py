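import numpy as np
import pytest
from scipy.stats import chisquare

from grid3d.analysis3d import (
    PLANE_ANGLE,
    analyze_map,
    autocorr3d,
    best_plane,
    count_hex_planes,
    count_symmetric_pairs,
    empirical_cost,
    fcc_hcp_scores,
    find_peaks3d,
    first_shell,
    local_gridness,
    poisson_spikes,
    population_alignment,
    spacing_from_autocorr,
)
from grid3d.analytic_cost import KernelParams, LatticeSpec, cost
from grid3d.fixtures import make_fixture
from grid3d.maps import RateMap3D


class TestAutocorr:
    def test_normalization_and_symmetry(self, fcc_ac):
        c = fcc_ac.center
        assert fcc_ac.corr[c] == pytest.approx(1.0)
        flipped = fcc_ac.corr[::-1, ::-1, ::-1]
        np.testing.assert_allclose(fcc_ac.corr, flipped, atol=1e-9, equal_nan=True)
        assert np.nanmax(np.abs(fcc_ac.corr)) <= 1.0 + 1e-12

    def test_constant_map_has_no_correlation(self):
        m = RateMap3D(np.full((12, 12, 12), 0.4))
        with pytest.warns(UserWarning):
            ac = autocorr3d(m)
        assert np.isnan(ac.corr).all()

    def test_masked_voxels_are_excluded(self, rng):
        vals = rng.uniform(0, 1, (16, 16, 16))
        vals[:3] = np.nan
        ac = autocorr3d(RateMap3D(vals))
        assert np.isfinite(ac.corr[ac.center])
        # displacements with too little overlap are masked
        assert np.isnan(ac.corr[0, 0, 0])

    def test_spacing_recovers_lattice_constant(self, fcc_ac, hcp_ac):
        assert spacing_from_autocorr(fcc_ac) == pytest.approx(0.3, rel=0.05)
        assert spacing_from_autocorr(hcp_ac) == pytest.approx(0.3, rel=0.05)


class TestPeaks:
    def test_fcc_first_shell_six_symmetric_pairs(self, fcc_ac):
        d = spacing_from_autocorr(fcc_ac)
        disp, vals = find_peaks3d(fcc_ac)
        shell, _ = first_shell(disp, vals, d)
        assert len(shell) == 12
        assert count_symmetric_pairs(shell, tol=0.25 * d) == 6

    def test_hcp_first_shell_nine_pairs(self, hcp_ac):
        d = spacing_from_autocorr(hcp_ac)
        disp, vals = find_peaks3d(hcp_ac)
        shell, _ = first_shell(disp, vals, d)
        assert len(shell) == 18
        assert count_symmetric_pairs(shell, tol=0.25 * d) == 9


class TestBestPlane:
    def test_hcp_normal_is_stacking_axis(self, hcp_ac):
        bp = best_plane(hcp_ac)
        assert bp.found and bp.score > 0.9
        angle = np.degrees(np.arccos(min(abs(bp.normal[2]), 1.0)))
        assert angle < 3.0

    def test_planar_hexagonal_pattern_scores_high(self):
        m = make_fixture("planar-hex", a=0.3, resolution=48)
        bp = best_plane(autocorr3d(m))
        assert bp.score > 0.9
        assert abs(bp.normal[2]) > 0.95

    def test_null_fixtures_score_low(self):
        """Chance level of the best-plane search, frozen from the measured
        null distribution (noise and voxel-shuffled fixtures)."""
        for kind in ("noise", "shuffled"):
            for seed in (0, 1):
                m = make_fixture(kind, resolution=48, rng=np.random.default_rng(seed))
                bp = best_plane(autocorr3d(m))
                assert bp.score < 0.6

    def test_undetectable_ring_flagged(self, rng):
        # a single central blob has no secondary peak ring
        x = np.linspace(-1, 1, 24)
        X = np.stack(np.meshgrid(x, x, x, indexing="ij"), axis=-1)
        m = RateMap3D(np.exp(-np.sum(X**2, -1) / 0.02))
        bp = best_plane(autocorr3d(m))
        assert not bp.found and bp.score == 0.0


class TestOrderScores:
    def test_fcc_fixture_scores(self, fcc_ac):
        gs = fcc_hcp_scores(fcc_ac, best_plane(fcc_ac))
        assert gs.zeta_24 > 2.0
        assert gs.chi_fcc > 0.8
        assert gs.chi_hcp < 0.3

    def test_hcp_fixture_scores(self, hcp_ac):
        gs = fcc_hcp_scores(hcp_ac, best_plane(hcp_ac))
        assert gs.chi_hcp > 0.8
        assert gs.chi_fcc < 0.3
        # interlayer distance close to sqrt(2/3) d
        assert gs.lambda_z == pytest.approx(np.sqrt(2 / 3) * gs.d, rel=0.1)

    def test_hex_plane_counts(self, fcc_ac, hcp_ac):
        assert count_hex_planes(fcc_ac, best_plane(fcc_ac)) == 4
        assert count_hex_planes(hcp_ac, best_plane(hcp_ac)) == 7

    def test_rotation_invariance(self, hcp_map):
        """Exact 90-degree lattice rotation leaves all scores unchanged."""
        rot = RateMap3D(np.rot90(hcp_map.rates, k=1, axes=(0, 2)).copy())
        g1 = analyze_map(hcp_map)
        g2 = analyze_map(rot)
        assert g1.d == pytest.approx(g2.d, rel=0.02)
        assert g1.hex_score == pytest.approx(g2.hex_score, abs=0.02)
        assert g1.chi_fcc == pytest.approx(g2.chi_fcc, abs=0.1)
        assert g1.chi_hcp == pytest.approx(g2.chi_hcp, abs=0.1)

    def test_scale_invariance(self, fcc_map):
        scaled = RateMap3D(7.3 * fcc_map.rates)
        g1, g2 = analyze_map(fcc_map), analyze_map(scaled)
        assert g1.d == pytest.approx(g2.d, rel=1e-6)
        assert g1.hex_score == pytest.approx(g2.hex_score, abs=1e-9)
        assert g1.chi_fcc == pytest.approx(g2.chi_fcc, abs=1e-9)


class TestPoissonSpikes:
    def test_single_voxel_map_concentrates_spikes(self, rng):
        vals = np.zeros((8, 8, 8))
        vals[2, 5, 3] = 1.0
        s = poisson_spikes(RateMap3D(vals), 500, rng)
        idx = (s / (1.0 / 8)).astype(int)
        assert np.all(idx == [2, 5, 3])

    def test_counts_follow_rates(self, rng):
        vals = rng.uniform(0.1, 1.0, (6, 6, 6))
        m = RateMap3D(vals)
        s = poisson_spikes(m, 100_000, rng)
        idx = np.minimum((s * 6).astype(int), 5)
        flat = (idx[:, 0] * 6 + idx[:, 1]) * 6 + idx[:, 2]
        counts = np.bincount(flat, minlength=216)
        expected = vals.ravel() / vals.sum() * 100_000
        assert chisquare(counts, expected).pvalue > 0.01

    def test_seeded_reproducibility(self, fcc_map):
        a = poisson_spikes(fcc_map, 1000, np.random.default_rng(5))
        b = poisson_spikes(fcc_map, 1000, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_zero_map_rejected(self, rng):
        with pytest.raises(ValueError):
            poisson_spikes(RateMap3D(np.zeros((4, 4, 4))), 10, rng)


class TestLocalGridness:
    def test_fcc_spikes_recover_spacing_and_hexagonal_angle(self, rng):
        # sharply peaked fields (n = 10) so spike jitter stays well below
        # the field spacing
        m = make_fixture("fcc", a=0.3, resolution=48, n=10)
        spikes = poisson_spikes(m, 4000, rng)
        lg = local_gridness(spikes, rng=rng)
        assert lg.d == pytest.approx(0.3, rel=0.05)
        assert lg.char_angle == pytest.approx(60.0, abs=6.0)
        assert lg.significance > 1.5

    def test_uniform_spikes_are_chance_level(self, rng):
        spikes = rng.uniform(0, 1, size=(2500, 3))
        lg = local_gridness(spikes, rng=rng)
        # control equals data by construction: ratio ~ 1 everywhere
        assert not np.isfinite(lg.significance) or lg.significance < 1.35

    def test_too_few_spikes_rejected(self, rng):
        with pytest.raises(ValueError):
            local_gridness(rng.uniform(0, 1, (100, 3)), rng=rng)


class TestPopulationAlignment:
    def test_identical_units_fully_aligned(self):
        n = np.array([0.0, 0.0, 1.0])
        ax = np.array([1.0, 0.0, 0.0])
        betas, omegas = population_alignment([n] * 5, [ax] * 5)
        np.testing.assert_allclose(betas, 0.0, atol=1e-9)
        np.testing.assert_allclose(omegas, 0.0, atol=1e-9)

    def test_random_planes_match_analytic_mean_angle(self, rng):
        """Mean angle between random lines in 3D is exactly 1 radian."""
        v = rng.standard_normal((300, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        betas, _ = population_alignment(list(v), [None] * 300)
        assert np.mean(betas) == pytest.approx(np.degrees(1.0), rel=0.02)

    def test_coaligned_planes_with_rotated_axes(self):
        n = np.array([0.0, 0.0, 1.0])
        axes = [np.array([np.cos(t), np.sin(t), 0.0]) for t in (0.0, np.pi / 3, 2 * np.pi / 3)]
        betas, omegas = population_alignment([n] * 3, axes)
        np.testing.assert_allclose(betas, 0.0, atol=1e-9)
        np.testing.assert_allclose(omegas, 0.0, atol=1e-6)  # 60 deg = hexagonal identity


class TestEmpiricalCost:
    def test_constant_map_costs(self):
        params = KernelParams(vtau_L=0.02, vtau_S=0.02 / 3, rho=0.03)
        m = RateMap3D(np.full((50, 50, 50), 0.5))
        hk, ha = empirical_cost(m, params)
        assert hk == 0.0
        # c^2 (1 - rho), reduced slightly by boundary truncation of the kernel
        ideal = 0.25 * (1 - 0.03)
        assert ha < ideal
        assert ha == pytest.approx(ideal, rel=0.05)

    def test_kinetic_term_matches_analytic_route(self):
        """H_K of the voxelized psi_FCC (n=1) map agrees with the exact
        Fourier-mode value within discretization error."""
        spec = LatticeSpec("fcc", a=0.5, n=1)
        m = make_fixture("fcc", a=0.5, resolution=64, n=1)
        hk_map, _ = empirical_cost(m, KernelParams(vtau_L=0.1, vtau_S=0.033, rho=0.03))
        hk_exact, _, _ = cost(spec, 0.0, KernelParams())
        assert hk_map == pytest.approx(hk_exact, rel=0.02)
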