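import numpy as np
import pytest

from cbctmc.correction import (
    CorrectionConfig,
    CorrectionParams,
    IterationState,
    corrected_log_projection,
    grid_beta,
    run_correction,
    run_iteration,
    simulate_scan,
)
from cbctmc.geometry import ConeBeamGeometry, ProjectionImage
from cbctmc.materials import make_water_air_phantom
from cbctmc.recon import LogProjection, ReconGrid
from cbctmc.transport import Spectrum, VRTParams


def _img(arr, comp="primary"):
    return ProjectionImage(np.asarray(arr, float), comp, 0.0)


def _log(arr):
    return LogProjection(np.asarray(arr, float), 0.0, "raw")


class TestCorrectedLogProjection:
    def test_zero_scatter_is_identity(self):
        r = _log(np.random.default_rng(0).random((4, 4)) + 1)
        p = corrected_log_projection(
            r, _log(np.zeros((4, 4))), _img(np.ones((4, 4))),
            _img(np.zeros((4, 4)), "scatter"),
            CorrectionParams(alpha=0.0, beta=0.7))
        np.testing.assert_allclose(p.pixels, r.pixels)

    def test_equal_primary_scatter_adds_ln2(self):
        r = _log(np.full((3, 3), 1.5))
        p = corrected_log_projection(
            r, _log(np.zeros((3, 3))), _img(np.full((3, 3), 2.0)),
            _img(np.full((3, 3), 2.0), "scatter"),
            CorrectionParams(alpha=0.0, beta=1.0))
        np.testing.assert_allclose(p.pixels, 1.5 + np.log(2.0))

    def test_hand_evaluated_example(self):
        # (1.5)(2.0) - 0.5*1.8 - ln(1.0/1.2) = 2.28232...
        p = corrected_log_projection(
            _log([[2.0]]), _log([[1.8]]), _img([[1.0]]),
            _img([[0.4]], "scatter"),
            CorrectionParams(alpha=0.5, beta=0.5))
        assert p.pixels[0, 0] == pytest.approx(3.0 - 0.9 + np.log(1.2),
                                               abs=1e-12)
        assert p.pixels[0, 0] == pytest.approx(2.28232, abs=1e-5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            corrected_log_projection(
                _log(np.ones((3, 3))), _log(np.ones((4, 4))),
                _img(np.ones((3, 3))), _img(np.ones((3, 3)), "scatter"),
                CorrectionParams())

    def test_beta_enters_only_through_ln(self):
        rng = np.random.default_rng(1)
        r = _log(rng.random((5, 5)))
        rs = _log(rng.random((5, 5)))
        P = _img(rng.random((5, 5)) + 0.5)
        S = rng.random((5, 5))
        a = corrected_log_projection(r, rs, P, _img(0.6 * S, "scatter"),
                                     CorrectionParams(alpha=0.0, beta=1.0))
        b = corrected_log_projection(r, rs, P, _img(S, "scatter"),
                                     CorrectionParams(alpha=0.0, beta=0.6))
        np.testing.assert_allclose(a.pixels, b.pixels, rtol=1e-12)


class TestGridBeta:
    def test_no_grid_unity(self):
        assert grid_beta(1.3, 1.3) == 1.0

    def test_ten_to_one_grid_half(self):
        # published SPR reduction for a 10:1 grid at this geometry
        assert grid_beta(0.5, 1.0) == pytest.approx(0.5)

    def test_identity_with_spr(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            P, S, beta = rng.random(3) + 0.01
            lhs = P / (P + beta * S)
            rhs = 1.0 / (1.0 + beta * (S / P))
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            grid_beta(0.5, 0.0)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            CorrectionParams(beta=0.0)
        with pytest.raises(ValueError):
            CorrectionParams(max_iter=-1)
        with pytest.raises(ValueError):
            CorrectionParams(conv_tol=0.0)
        with pytest.raises(ValueError):
            IterationState(iteration=-1, volume=None)


@pytest.fixture(scope="module")
def tiny_config():
    geom = ConeBeamGeometry(100.0, 149.88, (39.7, 29.8), (32, 24), 0, 360, 12)
    grid = ReconGrid((32, 32, 16), (22 / 32, 22 / 32, 22 / 32))
    return CorrectionConfig(
        geometry=geom, spectrum=Spectrum.monoenergetic(60.0),
        recon_grid=grid, vrt=VRTParams(n_split=8, rr_factor=4),
        n_histories=5_000, seed=0)


class TestIterationLoop:
    def test_max_iter_zero_returns_initial_only(self, tiny_config):
        ph = make_water_air_phantom(20, 20, 0, 0, voxel_size=22 / 32,
                                    shape=(32, 32, 32))
        raw = simulate_scan(ph, tiny_config, include_scatter=False)
        params = CorrectionParams(alpha=0.0, beta=1.0, max_iter=0)
        states, trace = run_correction(raw, params, tiny_config)
        assert len(states) == 1
        assert states[0].iteration == 0
        assert len(trace) == 1

    def test_vacuum_fixed_point(self, tiny_config):
        # no object: zero simulated scatter, so the correction is exact
        ph = make_water_air_phantom(20, 20, 0, 0, voxel_size=22 / 32,
                                    shape=(32, 32, 32))
        ph.density[:] = 0.0
        ph.material_index[:] = 0
        raw = simulate_scan(ph, tiny_config)
        params = CorrectionParams(alpha=0.0, beta=1.0, max_iter=1,
                                  conv_tol=1e-12)
        states, _ = run_correction(raw, params, tiny_config)
        np.testing.assert_allclose(states[-1].volume.mu, states[0].volume.mu,
                                   atol=1e-9)

    def test_state_counting(self, tiny_config):
        ph = make_water_air_phantom(20, 20, 0, 0, voxel_size=22 / 32,
                                    shape=(32, 32, 32))
        raw = simulate_scan(ph, tiny_config)
        params = CorrectionParams(alpha=0.0, beta=1.0, max_iter=3,
                                  conv_tol=1e-12)
        states, trace = run_correction(raw, params, tiny_config)
        assert [s.iteration for s in states] == list(range(len(states)))
        assert len(states) <= 4

    def test_run_iteration_requires_volume(self, tiny_config):
        with pytest.raises(ValueError):
            run_iteration(IterationState(0, None), None,
                          CorrectionParams(), tiny_config)


class TestReplicateShortcut:
    def test_symmetric_phantom_consistency(self):
        # rotationally symmetric phantom: replicating the first angle must
        # agree with per-angle simulation within statistical uncertainty
        geom = ConeBeamGeometry(100.0, 149.88, (39.7, 29.8), (48, 36),
                                0, 360, 16)
        grid = ReconGrid((48, 48, 16), (22 / 48, 22 / 48, 22 / 48))
        ph = make_water_air_phantom(20, 20, 2, 10, voxel_size=22 / 48,
                                    shape=(48, 48, 48))
        vols = {}
        for replicate in (True, False):
            cc = CorrectionConfig(
                geometry=geom, spectrum=Spectrum.monoenergetic(60.0),
                recon_grid=grid, vrt=VRTParams(16, 8), n_histories=40_000,
                replicate_symmetric=replicate, seed=3)
            raw = simulate_scan(ph, cc)
            from cbctmc.recon import air_normalize, fdk_reconstruct
            lps = [LogProjection(
                air_normalize(raw.get(a, "total"), raw.get(a, "blank")).pixels,
                a, "raw") for a in raw.angles("total")]
            vols[replicate] = fdk_reconstruct(lps, geom, grid,
                                              hu_scale=cc.mu_water)
        a, b = vols[True].mu[:, :, 8], vols[False].mu[:, :, 8]
        xs = (np.arange(48) + 0.5) / 48 - 0.5
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        mask = X ** 2 + Y ** 2 < 0.4 ** 2
        # means agree within the combined statistical uncertainty of the
        # two scatter estimates (~1.5% of water attenuation at 4e4 histories)
        assert abs(a[mask].mean() - b[mask].mean()) < 0.015 * 0.206
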