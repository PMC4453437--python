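import numpy as np
import pytest
from scipy.integrate import quad
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from grid3d.analytic_cost import (
    _mode_basis,
    HCP_PERFECT_RATIO,
    CostFit,
    KernelParams,
    LatticeSpec,
    cost,
    fcc_wavevectors,
    fit_cost_timecourse,
    fourier_modes,
    hcp_wavevectors,
    kernel_ft,
    kernel_real,
    lattice_points,
    optimize_lattice,
    psi,
)


class TestWaveVectors:
    def test_fcc_magnitudes(self):
        k = fcc_wavevectors(a=0.7)
        np.testing.assert_allclose(
            np.sum(k**2, axis=1), 1.5 * (2 * np.pi / 0.7) ** 2, rtol=1e-12
        )

    def test_fcc_tetrahedral_sum_is_zero(self):
        np.testing.assert_allclose(fcc_wavevectors(1.0).sum(axis=0), 0.0, atol=1e-12)

    def test_hcp_magnitudes_and_perfect_ratio(self):
        kxy, kz = hcp_wavevectors(a=1.3)
        np.testing.assert_allclose(
            np.sum(kxy**2, axis=1), (4.0 / 3.0) * (2 * np.pi / 1.3) ** 2, rtol=1e-12
        )
        ratio = np.linalg.norm(kz) / np.linalg.norm(kxy[0])
        assert ratio == pytest.approx(HCP_PERFECT_RATIO, rel=1e-12)
        assert HCP_PERFECT_RATIO == pytest.approx(3 / np.sqrt(32), rel=1e-15)


class TestPsi:
    @pytest.mark.parametrize("kind", ["fcc", "hcp"])
    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_unit_mean_and_nonnegative(self, kind, n, rng):
        spec = LatticeSpec(kind, a=0.4, n=n)
        vals = psi(_cell_points(spec, rng, 200_000), spec)
        assert vals.mean() == pytest.approx(1.0, abs=0.01)
        assert vals.min() >= -1e-9

    def test_fcc_base_value_at_origin(self):
        # 1 + (1/4)*4 = 2 before normalization; p_1 = 1 (mean already 1)
        assert psi(np.zeros(3), LatticeSpec("fcc", a=1.0, n=1)) == pytest.approx(2.0)

    def test_invalid_power_rejected(self):
        with pytest.raises(ValueError):
            LatticeSpec("fcc", n=0)


class TestKernel:
    def test_dc_value(self):
        p = KernelParams()
        assert kernel_ft(0.0, p) == pytest.approx(1 - p.rho)

    def test_rho_zero_is_pure_gaussian(self):
        p = KernelParams(vtau_L=0.8, vtau_S=0.1, rho=0.0)
        k = np.linspace(0, 10, 7)
        np.testing.assert_allclose(kernel_ft(k, p), np.exp(-0.5 * (k * 0.8) ** 2))

    def test_matches_radial_quadrature(self):
        """3D Fourier integral of the real-space kernel at k = 2 pi."""
        p = KernelParams()
        k = 2 * np.pi
        integrand = lambda r: 4 * np.pi * r * kernel_real(r, p) * np.sin(k * r) / k
        val, _ = quad(integrand, 0, 12, limit=400)
        assert val == pytest.approx(kernel_ft(k, p), abs=1e-6)


def _cell_points(spec, rng, n_pts, shift=0.0):
    """Uniform sample over one periodic unit cell (exact cell mean)."""
    K = _mode_basis(spec)
    B = 2 * np.pi * np.linalg.inv(K)
    u = rng.uniform(0, 1, size=(n_pts, 3))
    return u @ B.T + shift


def _mc_kinetic(spec, rng, n_pts=150_000, h=2e-5, shift=0.0):
    """Independent oracle: <|grad psi|^2> by central differences + Monte Carlo
    over one periodic unit cell."""
    x = _cell_points(spec, rng, n_pts, shift)
    acc = np.zeros(n_pts)
    for d in range(3):
        e = np.zeros(3)
        e[d] = h
        acc += ((psi(x + e, spec) - psi(x - e, spec)) / (2 * h)) ** 2
    return acc.mean()


class TestCost:
    def test_gamma_zero_leaves_kinetic_term_only(self):
        spec = LatticeSpec("fcc", a=1.0, n=2)
        hk, ha, h = cost(spec, 0.0, KernelParams())
        assert h == hk

    @pytest.mark.parametrize("kind,n", [("fcc", 1), ("fcc", 2), ("hcp", 2)])
    def test_kinetic_term_matches_quadrature_oracle(self, kind, n, rng):
        spec = LatticeSpec(kind, a=1.0, n=n)
        hk, _, _ = cost(spec, 0.0, KernelParams())
        assert _mc_kinetic(spec, rng) == pytest.approx(hk, rel=5e-3)

    def test_n2_fcc_kinetic_coefficient(self, rng):
        """The n=2 FCC kinetic term is an exact rational multiple of k^2
        (denominator 162); the Fourier expansion and the Monte-Carlo
        quadrature oracle agree on the numerator."""
        spec = LatticeSpec("fcc", a=1.0, n=2)
        hk, _, _ = cost(spec, 0.0, KernelParams())
        k2 = 1.5 * (2 * np.pi) ** 2
        numer = hk / k2 * 162
        assert numer == pytest.approx(round(numer), abs=1e-9)
        assert _mc_kinetic(spec, rng) / k2 * 162 == pytest.approx(numer, rel=5e-3)

    def test_adaptation_term_matches_realspace_filtering(self):
        """psi_FCC is Cartesian-periodic on a (sqrt3, 1, sqrt6)*a box, so the
        double integral psi K psi can be evaluated independently by wrapped
        difference-of-Gaussians filtering on a fine grid."""
        spec = LatticeSpec("fcc", a=1.0, n=2)
        params = KernelParams(vtau_L=0.21, vtau_S=0.07, rho=0.03)
        box = np.array([np.sqrt(3.0), 1.0, np.sqrt(6.0)])
        shape = np.round(box / 0.02).astype(int)
        axes = [np.arange(s) / s * b for s, b in zip(shape, box)]
        X = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        f = psi(X, spec)
        vox = box / shape
        kf = gaussian_filter(f, params.vtau_L / vox, mode="wrap", truncate=6.0)
        kf -= params.rho * gaussian_filter(f, params.vtau_S / vox, mode="wrap", truncate=6.0)
        ha_real = float(np.mean(f * kf))
        _, ha_fourier, _ = cost(spec, 1.0, params, include_dc=True)
        assert ha_real == pytest.approx(ha_fourier, rel=5e-3)

    def test_translation_invariance(self, rng):
        """The kinetic energy density is invariant under translations of the
        field (checked against the shifted-field quadrature)."""
        spec = LatticeSpec("hcp", a=1.0, n=2)
        hk, _, _ = cost(spec, 0.0, KernelParams())
        shift = rng.uniform(0, 3, 3)
        assert _mc_kinetic(spec, rng, n_pts=250_000, shift=shift) == pytest.approx(hk, rel=1.5e-2)


class TestLatticePoints:
    @pytest.mark.parametrize("kind", ["fcc", "hcp"])
    def test_interior_points_have_12_nearest_neighbors(self, kind):
        a = 1.0
        pts = lattice_points(kind, a, extent=8.0)
        tree = cKDTree(pts)
        interior = pts[np.all(np.abs(pts) < 2.5, axis=1)]
        assert len(interior) > 20
        for p in interior:
            nb = tree.query_ball_point(p, r=1.05 * a)
            assert len(nb) - 1 == 12
            d = np.linalg.norm(pts[nb] - p, axis=1)
            d = d[d > 1e-9]
            np.testing.assert_allclose(d, a, rtol=1e-9)

    def test_interlayer_spacing(self):
        pts = lattice_points("fcc", 1.0, extent=6.0)
        zs = np.unique(np.round(pts[:, 2], 9))
        np.testing.assert_allclose(np.diff(zs), np.sqrt(2.0 / 3.0), rtol=1e-9)

    def test_fcc_centrally_symmetric_hcp_not(self):
        for kind, expect in (("fcc", True), ("hcp", False)):
            pts = lattice_points(kind, 1.0, extent=7.0)
            tree = cKDTree(pts)
            # reflect through one lattice site near the center
            site = pts[np.argmin(np.linalg.norm(pts, axis=1))]
            inner = pts[np.all(np.abs(pts - site) < 2.0, axis=1)]
            refl = 2 * site - inner
            d, _ = tree.query(refl)
            assert bool(np.max(d) < 1e-9) is expect


class TestOptimization:
    def test_hcp_n1_prefers_columnar_solution(self):
        params = KernelParams()
        for gamma in (30.0, 300.0, 3000.0):
            r = optimize_lattice("hcp", 1, gamma, params)
            assert r["ratio"] == pytest.approx(0.0, abs=1e-3)

    def test_hcp_high_power_ratio_near_close_packing(self):
        r = optimize_lattice("hcp", 6, 2000.0, KernelParams())
        assert r["ratio"] == pytest.approx(HCP_PERFECT_RATIO, abs=0.08)

    def test_fcc_minimizer_stable_under_restart(self):
        params = KernelParams()
        a_stars = [
            optimize_lattice("fcc", 2, 100.0, params, a_bounds=b)["a"]
            for b in ((0.05, 20.0), (0.1, 12.0), (0.5, 8.0))
        ]
        assert max(a_stars) - min(a_stars) < 1e-4

    def test_optimal_spacing_decreases_with_gamma(self):
        params = KernelParams()
        a_fcc = [optimize_lattice("fcc", 2, g, params)["a"] for g in (30, 100, 300, 1000)]
        assert all(b < a for a, b in zip(a_fcc, a_fcc[1:]))


class TestCostFit:
    def _series(self, rng, noise=0.01):
        t = np.linspace(0, 30, 60)
        true = dict(A=2.0, B=0.8, C=1.5, D=0.9, E=0.5, K=0.3,
                    tau_S=1.2, tau_M=4.0, tau_L=12.0)
        hk = true["A"] * np.exp(-t / true["tau_S"]) + true["B"] * np.exp(-t / true["tau_L"]) + true["K"]
        ha = true["C"] * np.exp(-t / true["tau_S"]) - true["D"] * np.exp(-t / true["tau_M"]) + true["E"]
        hk = hk * (1 + noise * rng.standard_normal(len(t)))
        ha = ha * (1 + noise * rng.standard_normal(len(t)))
        return t, hk, ha, true

    def test_parameter_recovery_within_ten_percent(self, rng):
        t, hk, ha, true = self._series(rng)
        fit = fit_cost_timecourse(t, hk, ha)
        for name, v in true.items():
            assert getattr(fit, name) == pytest.approx(v, rel=0.1), name

    def test_constant_series_yields_unbounded_gamma(self):
        t = np.linspace(0, 10, 25)
        fit = fit_cost_timecourse(t, np.full(25, 2.0), np.full(25, 0.7))
        assert fit.gamma_star == np.inf
        assert fit.A == fit.B == fit.C == fit.D == 0

    def test_combined_cost_monotone_at_gamma_star(self, rng):
        t, hk, ha, _ = self._series(rng)
        fit = fit_cost_timecourse(t, hk, ha)
        assert np.isfinite(fit.gamma_star) and fit.gamma_star > 0
        tt = np.linspace(t[0], t[-1] * 3, 2000)
        total = fit.hk(tt) + fit.gamma_star * fit.ha(tt)
        assert np.all(np.diff(total) <= 1e-9 * max(1.0, abs(total[0])))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_cost_timecourse(np.arange(10), np.arange(10.0), np.arange(10.0))
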