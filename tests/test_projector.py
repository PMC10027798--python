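"""Forward model: attenuation, CDR stacks, projector algebra, scatter, noise."""

from dataclasses import replace

import numpy as np
import pytest

from tandemspect.grid import VolumeImage, VoxelGrid
from tandemspect.nuclides import AC225, LU177
from tandemspect.projector import (
    AC225_WINDOWS,
    LU177_WINDOWS,
    AcquisitionGeometry,
    EnergyWindow,
    EnergyWindowSet,
    PsfStack,
    SpectProjector,
    add_poisson_noise,
    analytic_psf_stack,
    crosstalk_fraction,
    default_scatter_model,
    emulate_scatter_windows,
    forward_project,
    mu_map_from_density,
    water_mass_attenuation,
)


class TestAttenuation:
    def test_air_gives_zero_mu(self, small_grid):
        density = VolumeImage(small_grid, np.zeros(small_grid.shape),
                              "density_g_per_ml")
        mu = mu_map_from_density(density, 208.0)
        assert mu.quantity == "mu_per_mm"
        assert np.all(mu.values == 0)

    # NIST water mass-attenuation lookups (log-log interpolated)
    @pytest.mark.parametrize("energy, expected", [(208.0, 0.0137), (440.0, 0.0101)])
    def test_water_mu_per_mm(self, small_grid, energy, expected):
        density = VolumeImage(small_grid, np.ones(small_grid.shape),
                              "density_g_per_ml")
        mu = mu_map_from_density(density, energy)
        assert mu.values[0, 0, 0] == pytest.approx(expected, rel=0.02)

    def test_energy_outside_table_raises(self):
        with pytest.raises(ValueError):
            water_mass_attenuation(10.0)


class TestPsfStack:
    def test_fwhm_at_zero_distance_is_intrinsic(self):
        # fine pitch so the kernel resolves its own width
        stack = analytic_psf_stack("gaussian", intrinsic_fwhm_mm=6.0,
                                   n_planes=10, max_distance_mm=100.0,
                                   pitch_mm=(1.0, 1.0))
        k = stack.kernel_for(0.0)
        profile = k[:, k.shape[1] // 2]
        half = profile.max() / 2
        above = np.where(profile >= half)[0]
        # linear interpolation at the half-max crossings
        lo = above[0] - (profile[above[0]] - half) / \
            (profile[above[0]] - profile[above[0] - 1])
        hi = above[-1] + (profile[above[-1]] - half) / \
            (profile[above[-1]] - profile[above[-1] + 1])
        assert hi - lo == pytest.approx(6.0, abs=0.3)

    def test_fwhm_grows_with_distance(self):
        stack = analytic_psf_stack("gaussian", intrinsic_fwhm_mm=4.0, slope=0.09)
        second_moment = []
        for d in (0.0, 300.0, 600.0):
            k = stack.kernel_for(d)
            x = np.arange(k.shape[0]) - k.shape[0] // 2
            second_moment.append(float((k.sum(axis=1) * x**2).sum()))
        assert second_moment[0] < second_moment[1] < second_moment[2]

    def test_zero_penetration_equals_gaussian(self):
        kw = dict(intrinsic_fwhm_mm=4.0, slope=0.09, n_planes=20)
        g = analytic_psf_stack("gaussian", **kw)
        he = analytic_psf_stack("high_energy", penetration_fraction=0.0, **kw)
        for kg, kh in zip(g.kernels, he.kernels):
            np.testing.assert_allclose(kh, kg)

    def test_arm_fraction_matches_penetration(self):
        kw = dict(intrinsic_fwhm_mm=4.0, slope=0.09, n_planes=20)
        p = 0.3
        he = analytic_psf_stack("high_energy", penetration_fraction=p, **kw)
        g = analytic_psf_stack("gaussian", **kw)
        for kh, kg in zip(he.kernels, g.kernels):
            core = np.zeros_like(kh)
            off = tuple((np.array(kh.shape) - kg.shape) // 2)
            core[off[0]:off[0] + kg.shape[0], off[1]:off[1] + kg.shape[1]] = kg
            arm_mass = float((kh - (1 - p) * core).sum())
            assert arm_mass == pytest.approx(p, abs=0.01)

    def test_kernels_normalized_and_centrosymmetric(self):
        he = analytic_psf_stack("high_energy", penetration_fraction=0.25,
                                n_planes=10)
        for k in he.kernels:
            assert k.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(k, k[::-1, ::-1], atol=1e-15)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            analytic_psf_stack("high_energy", penetration_fraction=1.0)
        with pytest.raises(ValueError):
            analytic_psf_stack("nope")


@pytest.fixture()
def geom():
    return AcquisitionGeometry(n_views=4, heads=2, time_per_view_s=100.0)


class TestProjector:
    def test_point_source_view_totals(self, small_grid, geom):
        act = np.zeros(small_grid.shape)
        act[8, 8, 6] = 1e6  # Bq/ml
        img = VolumeImage(small_grid, act, "activity_conc_Bq_per_ml")
        p = forward_project(img, None, PsfStack.delta(), geom, 22.7)
        expected = 1e6 * small_grid.voxel_volume_ml * 1e-6 * 22.7 * 100.0
        np.testing.assert_allclose(p.views.sum(axis=(1, 2)), expected, rtol=1e-12)

    def test_beer_lambert_attenuation(self):
        grid = VoxelGrid.centered((32, 32, 16), (4.0,) * 3)
        g1 = AcquisitionGeometry(n_views=1, heads=1, time_per_view_s=10.0)
        src = np.zeros(grid.shape)
        src[16, 16, 8] = 1e6
        img = VolumeImage(grid, src, "activity_conc_Bq_per_ml")
        muv = np.zeros(grid.shape)
        muv[:, 20:25, :] = 0.0137  # 5-voxel water slab toward the detector
        mu = VolumeImage(grid, muv, "mu_per_mm")
        free = forward_project(img, None, PsfStack.delta(), g1, 1.0)
        att = forward_project(img, mu, PsfStack.delta(), g1, 1.0)
        assert att.views.sum() / free.views.sum() == pytest.approx(
            np.exp(-0.0137 * 5 * 4.0), rel=1e-9)

    def test_adjointness(self, small_grid, geom, rng):
        mu = VolumeImage(small_grid, rng.uniform(0, 0.01, small_grid.shape),
                         "mu_per_mm")
        psf = analytic_psf_stack("high_energy", penetration_fraction=0.3,
                                 n_planes=50)
        proj = SpectProjector(small_grid, geom, psf, mu, 22.7)
        x = rng.uniform(0, 1, small_grid.shape)
        y = rng.uniform(0, 1, (geom.total_views, small_grid.shape[0],
                               small_grid.shape[2]))
        lhs = float(np.sum(proj.forward(x) * y))
        rhs = float(np.sum(x * proj.adjoint(y)))
        assert abs(lhs - rhs) / lhs < 1e-6

    def test_linearity(self, small_grid, geom, rng):
        proj = SpectProjector(small_grid, geom,
                              analytic_psf_stack("gaussian", n_planes=30),
                              None, 1.0)
        a = rng.uniform(0, 1, small_grid.shape)
        b = rng.uniform(0, 1, small_grid.shape)
        np.testing.assert_allclose(proj.forward(2 * a + 3 * b),
                                   2 * proj.forward(a) + 3 * proj.forward(b),
                                   rtol=1e-10, atol=1e-12)

    def test_sensitivity_independent_of_position(self, small_grid, geom):
        # mu = 0, delta PSF: total counts over 360 deg do not depend on
        # where the object sits
        proj = SpectProjector(small_grid, geom, PsfStack.delta(), None, 22.7)
        a = np.zeros(small_grid.shape)
        a[8, 8, 6] = 1e6
        b = np.zeros(small_grid.shape)
        b[4, 10, 3] = 1e6
        ta, tb = proj.forward(a).sum(), proj.forward(b).sum()
        assert abs(ta - tb) / ta < 0.005

    def test_grid_mismatch_raises(self, small_grid, geom):
        act = VolumeImage(small_grid, np.ones(small_grid.shape),
                          "activity_conc_Bq_per_ml")
        other = VoxelGrid.centered((8, 8, 8), (4.7952,) * 3)
        mu = VolumeImage(other, np.zeros(other.shape), "mu_per_mm")
        with pytest.raises(ValueError):
            forward_project(act, mu, PsfStack.delta(), geom, 1.0)


class TestScatterEmulation:
    def _primary(self, small_grid, geom):
        act = np.zeros(small_grid.shape)
        act[6:10, 6:10, 4:8] = 5e4
        img = VolumeImage(small_grid, act, "activity_conc_Bq_per_ml")
        return forward_project(img, None, PsfStack.delta(), geom, 22.7)

    def test_zero_fraction_passthrough(self, small_grid, geom):
        prim = self._primary(small_grid, geom)
        out = emulate_scatter_windows(prim, AC225_WINDOWS, 0.0)
        np.testing.assert_array_equal(out["photopeak"].views, prim.views)
        assert np.all(out["lower"].views == 0)

    def test_dew_recovers_injected_scatter_exactly(self, small_grid, geom):
        from tandemspect.recon import dew_scatter_estimate
        prim = self._primary(small_grid, geom)
        out = emulate_scatter_windows(prim, AC225_WINDOWS, 0.5)
        injected = out["photopeak"].views - prim.views
        est = dew_scatter_estimate(out["lower"], AC225_WINDOWS)
        np.testing.assert_allclose(est.views, injected, rtol=1e-10, atol=1e-9)

    def test_tew_recovers_injected_scatter_exactly(self, small_grid, geom):
        from tandemspect.recon import tew_scatter_estimate
        prim = self._primary(small_grid, geom)
        out = emulate_scatter_windows(prim, LU177_WINDOWS, 0.3)
        injected = out["photopeak"].views - prim.views
        est = tew_scatter_estimate(out["lower"], out["upper"], LU177_WINDOWS)
        np.testing.assert_allclose(est.views, injected, rtol=1e-10, atol=1e-9)

    def test_linearity_in_scatter_fraction(self, small_grid, geom):
        prim = self._primary(small_grid, geom)
        o1 = emulate_scatter_windows(prim, AC225_WINDOWS, 0.25)
        o2 = emulate_scatter_windows(prim, AC225_WINDOWS, 0.5)
        np.testing.assert_allclose(o2["lower"].views, 2 * o1["lower"].views)

    def test_noisy_primary_rejected(self, small_grid, geom):
        prim = add_poisson_noise(self._primary(small_grid, geom), 1)
        with pytest.raises(ValueError, match="noiseless"):
            emulate_scatter_windows(prim, AC225_WINDOWS, 0.5)


class TestPoissonNoise:
    def test_zero_expectation_zero_counts(self, small_grid, geom):
        act = VolumeImage(small_grid, np.zeros(small_grid.shape),
                          "activity_conc_Bq_per_ml")
        p = forward_project(act, None, PsfStack.delta(), geom, 22.7)
        assert add_poisson_noise(p, 7).total_counts() == 0

    def test_seed_reproducibility(self, small_grid, geom, rng):
        act = VolumeImage(small_grid, rng.uniform(0, 1e4, small_grid.shape),
                          "activity_conc_Bq_per_ml")
        p = forward_project(act, None, PsfStack.delta(), geom, 22.7)
        n1 = add_poisson_noise(p, 123)
        n2 = add_poisson_noise(p, 123)
        np.testing.assert_array_equal(n1.views, n2.views)
        assert not np.array_equal(add_poisson_noise(p, 124).views, n1.views)

    def test_mean_over_many_seeds(self):
        # clinical Ac-225 count rate: 26 cps over 210 s per view = 5460 counts
        lam = 26.0 * 210.0
        draws = [np.random.default_rng(s).poisson(lam) for s in range(1000)]
        assert np.mean(draws) == pytest.approx(lam, rel=0.01)

    def test_lc_mode_divides_time(self, small_grid, geom):
        act = VolumeImage(small_grid, np.full(small_grid.shape, 1e4),
                          "activity_conc_Bq_per_ml")
        p = forward_project(act, None, PsfStack.delta(), geom, 22.7)
        lc = add_poisson_noise(p, 5, time_factor=30.0)
        assert lc.total_counts() == pytest.approx(p.views.sum() / 30.0, rel=0.05)
        assert lc.time_factor == 30.0


class TestEnergyWindows:
    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            EnergyWindowSet(EnergyWindow(208.0, 0.15),
                            (EnergyWindow(200.0, 0.15, "lower"),))

    def test_clinical_window_bounds(self):
        lo, hi = LU177_WINDOWS.photopeak.bounds_keV
        assert (lo, hi) == pytest.approx((192.4, 223.6))
        assert AC225_WINDOWS.photopeak.width_keV == pytest.approx(88.0)

    def test_crosstalk_below_one_percent_at_clinical_ratio(self):
        # Fr-221 218 keV lies inside the Lu-177 208 keV +/- 7.5 % window
        frac = crosstalk_fraction(
            LU177_WINDOWS.photopeak,
            contaminant=(8.0, AC225.photon_emissions),
            signal=(1000.0, LU177.photon_emissions))
        assert 0.0 < frac < 0.01
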