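import numpy as np
import pytest
from scipy import stats

from cbctmc.geometry import ConeBeamGeometry, ProjectionImage
from cbctmc.materials import make_water_air_phantom, volume_from_mu
from cbctmc.transport import (
    PhotonState,
    Spectrum,
    VRTParams,
    accept_real,
    adaptive_smooth,
    siddon_primary,
    simulate_projection,
    split_and_roulette,
    woodcock_free_path,
)


class TestSpectrum:
    def test_mono(self, mono60):
        assert mono60.energies[0] == 60.0
        assert mono60.mean_energy == 60.0

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([60.0, 80.0]), np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            Spectrum(np.array([5.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            Spectrum(np.array([]), np.array([]))


class TestSiddonPrimary:
    def test_vacuum_primary_equals_blank(self, small_geometry, mono60):
        ph = volume_from_mu(np.zeros((16, 16, 16)), voxel_size=(1, 1, 1))
        prim, blank = siddon_primary(ph, small_geometry, mono60, 0.0)
        np.testing.assert_allclose(prim.pixels, blank.pixels, rtol=1e-12)

    def test_beer_lambert_through_water(self, water_cylinder_64,
                                        small_geometry, mono60):
        prim, blank = siddon_primary(water_cylinder_64, small_geometry,
                                     mono60, 0.0)
        iv, iu = 12, 16
        trans = prim.pixels[iv, iu] / blank.pixels[iv, iu]
        # closed-form Beer-Lambert; 2% slack for voxelized chord length
        assert trans == pytest.approx(np.exp(-0.2059 * 20), rel=0.05)

    def test_tilted_slab_oblique_path(self, mono60):
        # 4 cm water slab normal to y, viewed at a 45-degree scan angle:
        # the central ray sees thickness / cos(45)
        from cbctmc.materials import make_ramp
        mu_w = 0.2059011
        ph = volume_from_mu(np.full((60, 8, 60), mu_w),
                            ramp=make_ramp(["Vacuum", "Air", "Water"], 60.0),
                            voxel_size=(0.5, 0.5, 0.5))
        geom = ConeBeamGeometry(100.0, 150.0, (40, 4), (64, 3), 0, 360, 8)
        prim, blank = siddon_primary(ph, geom, mono60, 45.0)
        iu = 31  # ~central column
        # dense 10-micron ray-marching oracle along the same pixel ray
        from cbctmc.geometry import pixel_ray
        src, d = pixel_ray(geom, 45.0, iu, 1)
        ts = np.arange(0, 160, 1e-3)
        pts = src[None, :] + ts[:, None] * d[None, :]
        inside = ((np.abs(pts[:, 0]) <= 15) & (np.abs(pts[:, 1]) <= 2)
                  & (np.abs(pts[:, 2]) <= 15))
        tau_march = inside.sum() * 1e-3 * mu_w
        tau_siddon = -np.log(prim.pixels[1, iu] / blank.pixels[1, iu])
        assert tau_siddon == pytest.approx(tau_march, rel=2e-3)
        # and the oblique path is close to 4 / cos(45 deg + small fan offset)
        assert tau_siddon / mu_w == pytest.approx(4 / np.cos(np.deg2rad(45)),
                                                  rel=0.02)


class TestWoodcock:
    def test_exponential_distribution_ks(self):
        rng = np.random.default_rng(0)
        mu = 0.31
        draws = np.array([woodcock_free_path(rng, mu) for _ in range(100_000)])
        assert stats.kstest(draws, "expon", args=(0, 1 / mu)).pvalue > 0.01

    def test_homogeneous_always_real(self):
        rng = np.random.default_rng(1)
        assert all(accept_real(0.2, 0.2, rng) for _ in range(100))

    def test_vacuum_always_fictitious(self):
        rng = np.random.default_rng(2)
        assert not any(accept_real(0.0, 0.2, rng) for _ in range(100))

    def test_invalid_mu_max(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            woodcock_free_path(rng, 0.0)
        with pytest.raises(ValueError):
            accept_real(0.3, 0.2, rng)


def _isotropic(rng):
    z = rng.uniform(-1, 1)
    phi = rng.uniform(0, 2 * np.pi)
    s = np.sqrt(1 - z * z)
    return np.array([s * np.cos(phi), s * np.sin(phi), z]), 60.0


class TestSplitAndRoulette:
    def test_identity_configuration(self):
        rng = np.random.default_rng(0)
        ph = PhotonState(np.zeros(3), np.array([0, 0, 1.0]), 60.0, 1.0)
        out = split_and_roulette(ph, VRTParams(n_split=1, rr_factor=1), rng,
                                 _isotropic, lambda d: False)
        assert len(out) == 1
        assert out[0].weight == pytest.approx(1.0)

    def test_survivor_weight_rule(self):
        rng = np.random.default_rng(1)
        ph = PhotonState(np.zeros(3), np.array([0, 0, 1.0]), 60.0, 1.0)
        vrt = VRTParams(n_split=10, rr_factor=5)
        for _ in range(50):
            for d in split_and_roulette(ph, vrt, rng, _isotropic,
                                        lambda d: d[2] > 0.9):
                if d.aimed:
                    assert d.weight == pytest.approx(1 / 10)
                else:
                    assert d.weight == pytest.approx(5 / 10)

    @pytest.mark.parametrize("n_split,rr", [(4, 2), (16, 8)])
    def test_weight_conserved_in_expectation(self, n_split, rr):
        rng = np.random.default_rng(42)
        ph = PhotonState(np.zeros(3), np.array([0, 0, 1.0]), 60.0, 1.0)
        vrt = VRTParams(n_split=n_split, rr_factor=rr)
        n = 20_000
        totals = np.empty(n)
        for i in range(n):
            totals[i] = sum(d.weight for d in split_and_roulette(
                ph, vrt, rng, _isotropic, lambda d: d[2] > 0.8))
        se = totals.std() / np.sqrt(n)
        assert abs(totals.mean() - 1.0) < 3 * se


class TestSimulateProjection:
    def test_vacuum_no_scatter(self, small_geometry, mono60):
        ph = volume_from_mu(np.zeros((8, 8, 8)), voxel_size=(1, 1, 1))
        prim_mc, scat = simulate_projection(ph, small_geometry, mono60, 0.0,
                                            5000, VRTParams(), seed=0)
        assert scat.pixels.sum() == 0.0
        prim, _ = siddon_primary(ph, small_geometry, mono60, 0.0)
        # expectation of the forced-detection primary is the ray-traced value
        assert prim_mc.pixels.sum() == pytest.approx(
            prim.pixels.sum(), rel=0.05)

    def test_primary_matches_siddon_3sigma(self, water_air_64,
                                           small_geometry, mono60):
        prim, _ = siddon_primary(water_air_64, small_geometry, mono60, 0.0)
        p_mc, _ = simulate_projection(water_air_64, small_geometry, mono60,
                                      0.0, 100_000, VRTParams(), seed=2)
        sig = p_mc.rel_uncertainty * p_mc.pixels
        ok = np.abs(p_mc.pixels - prim.pixels) <= 3 * np.maximum(sig, 1e-12)
        assert ok.mean() >= 0.99

    def test_splitting_unbiased(self, water_air_64, small_geometry, mono60):
        res = {}
        for n_split, rr in [(1, 1), (8, 4)]:
            _, s = simulate_projection(water_air_64, small_geometry, mono60,
                                       0.0, 60_000,
                                       VRTParams(n_split=n_split, rr_factor=rr),
                                       seed=5)
            err = np.sqrt(((s.rel_uncertainty * s.pixels) ** 2).sum())
            res[n_split] = (s.pixels.sum(), err)
        diff = abs(res[1][0] - res[8][0])
        comb = np.sqrt(res[1][1] ** 2 + res[8][1] ** 2)
        assert diff < 3 * comb
        # splitting reduces the per-pixel variance
        assert res[8][1] < res[1][1]

    def test_path_stretch_unbiased(self, water_air_64, small_geometry, mono60):
        base = simulate_projection(water_air_64, small_geometry, mono60, 0.0,
                                   60_000, VRTParams(), seed=9)[1]
        stretched = simulate_projection(
            water_air_64, small_geometry, mono60, 0.0, 60_000,
            VRTParams(path_stretch=0.5), seed=10)[1]
        comb = np.sqrt(((base.rel_uncertainty * base.pixels) ** 2).sum()
                       + ((stretched.rel_uncertainty * stretched.pixels) ** 2).sum())
        assert abs(base.pixels.sum() - stretched.pixels.sum()) < 4 * comb

    def test_scored_energy_bounded(self, water_air_64, small_geometry, mono60):
        _, s = simulate_projection(water_air_64, small_geometry, mono60, 0.0,
                                   20_000, VRTParams(), seed=3)
        nu, nv = small_geometry.det_pixels
        # mean scored scatter energy per history cannot exceed the source
        # energy (launch weights are <= 1)
        assert s.pixels.sum() / (nu * nv) <= 60.0

    def test_zero_histories_rejected(self, water_air_64, small_geometry,
                                     mono60):
        with pytest.raises(ValueError):
            simulate_projection(water_air_64, small_geometry, mono60, 0.0, 0,
                                VRTParams(), seed=0)

    def test_reproducible(self, water_air_64, small_geometry, mono60):
        a = simulate_projection(water_air_64, small_geometry, mono60, 0.0,
                                5_000, VRTParams(), seed=11)
        b = simulate_projection(water_air_64, small_geometry, mono60, 0.0,
                                5_000, VRTParams(), seed=11)
        np.testing.assert_array_equal(a[1].pixels, b[1].pixels)


class TestAdaptiveSmooth:
    def test_requires_uncertainty(self):
        img = ProjectionImage(np.ones((8, 8)), "scatter", 0.0)
        with pytest.raises(ValueError):
            adaptive_smooth(img)

    def test_constant_noiseless_fixed_point(self):
        img = ProjectionImage(np.full((32, 32), 7.0), "scatter", 0.0,
                              rel_uncertainty=np.zeros((32, 32)))
        out = adaptive_smooth(img)
        np.testing.assert_allclose(out.pixels, 7.0, atol=1e-9)

    def test_flat_noise_reduction(self):
        rng = np.random.default_rng(0)
        truth = np.full((48, 64), 10.0)
        noisy = truth * (1 + 0.05 * rng.standard_normal(truth.shape))
        img = ProjectionImage(np.maximum(noisy, 0), "scatter", 0.0,
                              rel_uncertainty=np.full(truth.shape, 0.05))
        out = adaptive_smooth(img)
        assert np.median(out.rel_uncertainty) <= 0.01

    def test_linear_ramp_preserved(self):
        rng = np.random.default_rng(1)
        X, _ = np.meshgrid(np.arange(64), np.arange(48))
        truth = 10 + 0.1 * X
        noisy = truth * (1 + 0.05 * rng.standard_normal(truth.shape))
        img = ProjectionImage(np.maximum(noisy, 0), "scatter", 0.0,
                              rel_uncertainty=np.full(truth.shape, 0.05))
        out = adaptive_smooth(img)
        assert np.sqrt(np.mean(((out.pixels - truth) / truth) ** 2)) < 0.01
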