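import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbctmc.materials import (
    Material,
    MaterialRamp,
    assign_material,
    default_ramp,
    load_ramp,
    make_catphan_like_phantom,
    make_ramp,
    make_water_air_phantom,
    material_mu,
    mu_to_density,
    volume_from_mu,
)

RAMP_ROWS = {
    # material -> (mu_mat, rho_mat) of the reference ramp
    "Vacuum": (0.0, 0.0),
    "Air": (5.18e-4, 1.205e-3),
    "PMP": (0.178, 0.83),
    "LDPE": (0.200, 0.93),
    "Polystyrene": (0.217, 1.06),
    "Water": (0.243, 1.00),
    "Acrylic": (0.259, 1.19),
    "Delrin": (0.315, 1.41),
    "Teflon": (0.485, 2.10),
}


class TestAssignMaterial:
    def test_water_row(self):
        assert assign_material(0.243).name == "Water"

    def test_vacuum_below_threshold(self):
        assert assign_material(1.0e-5).name == "Vacuum"

    def test_lower_bound_inclusive(self):
        assert assign_material(0.23).name == "Water"
        assert assign_material(0.251).name == "Acrylic"

    def test_negative_mu_rejected(self):
        with pytest.raises(ValueError):
            assign_material(-0.1)

    def test_ramp_round_trip_all_rows(self):
        for name, (mu_mat, rho_mat) in RAMP_ROWS.items():
            if name == "Vacuum":
                continue
            m = assign_material(mu_mat)
            assert m.name == name
            assert mu_to_density(mu_mat, m) == pytest.approx(rho_mat)


class TestMuToDensity:
    def test_ldpe_nominal(self, catalog):
        assert mu_to_density(0.200, catalog["LDPE"]) == pytest.approx(0.93)

    def test_vacuum_zero(self, catalog):
        assert mu_to_density(0.0, catalog["Vacuum"]) == 0.0

    def test_pmp_fractional(self, catalog):
        # 0.1 / 0.178 * 0.83, independent hand arithmetic
        assert mu_to_density(0.1, catalog["PMP"]) == pytest.approx(
            0.46629213, abs=1e-6)

    def test_negative_rejected(self, catalog):
        with pytest.raises(ValueError):
            mu_to_density(-1.0, catalog["Water"])


class TestVolumeFromMu:
    def test_all_zero_is_vacuum(self):
        ph = volume_from_mu(np.zeros((3, 3, 3)))
        assert all(ph.material_names[i] == "Vacuum"
                   for i in np.unique(ph.material_index))
        assert ph.density.max() == 0.0

    def test_uniform_water(self):
        ph = volume_from_mu(np.full((2, 2, 2), 0.243))
        names = np.asarray(ph.material_names)[ph.material_index]
        assert (names == "Water").all()
        np.testing.assert_allclose(ph.density, 1.0, rtol=1e-6)

    def test_two_voxel_hand_values(self):
        ph = volume_from_mu(np.array([[[0.1, 0.45]]]))
        names = np.asarray(ph.material_names)[ph.material_index][0, 0]
        assert list(names) == ["PMP", "Teflon"]
        np.testing.assert_allclose(
            ph.density[0, 0], [0.46629213, 0.45 / 0.485 * 2.10], rtol=1e-6)

    def test_negative_clamped(self, caplog):
        ph = volume_from_mu(np.array([[[-1e-4, 0.243]]]))
        assert ph.density[0, 0, 0] == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            volume_from_mu(np.array([[[np.nan]]]))

    def test_reassignment_idempotent(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(0, 0.6, size=(8, 8, 8))
        ph = volume_from_mu(mu)
        ramp = default_ramp()
        mu_mat = {e[2]: n[0] for e, n in zip(ramp.entries, ramp.nominals)}
        rho_mat = {e[2]: n[1] for e, n in zip(ramp.entries, ramp.nominals)}
        names = np.asarray(ph.material_names)[ph.material_index]
        # forward model at the reference spectrum then re-assign
        back = np.zeros_like(mu)
        for n in np.unique(names):
            if rho_mat[n] > 0:
                back[names == n] = (ph.density[names == n]
                                    / rho_mat[n] * mu_mat[n])
        ph2 = volume_from_mu(back)
        np.testing.assert_array_equal(ph.material_index, ph2.material_index)


class TestMaterialMu:
    def test_water_60kev_vs_published(self, catalog):
        # oracle: published XCOM/NIST value for liquid water at 60 keV
        assert material_mu(catalog["Water"], 60.0) == pytest.approx(
            0.2059, rel=0.01)

    def test_exact_at_grid_nodes(self, catalog):
        m = catalog["Teflon"]
        for e in (10.0, 60.0, 150.0):
            i = int(e - 10)
            assert material_mu(m, e) == pytest.approx(
                m.xs_total[i] * m.rho_nominal, rel=1e-9)

    def test_linear_in_density(self, catalog):
        m = catalog["Water"]
        assert m.mass_atten(77.3) * 2.0 == pytest.approx(
            2.0 * m.mass_atten(77.3))

    def test_out_of_range_energy(self, catalog):
        with pytest.raises(ValueError):
            material_mu(catalog["Water"], 5.0)
        with pytest.raises(ValueError):
            material_mu(catalog["Water"], 200.0)

    def test_interpolation_error_below_1pct_at_midpoints(self, catalog):
        # denser reference = full table; interpolate from every-2nd node
        m = catalog["Water"]
        coarse = Material(
            name="Water", mu_nominal=m.mu_nominal, rho_nominal=m.rho_nominal,
            xs_energy=m.xs_energy[::2], xs_total=m.xs_total[::2],
            xs_photo=m.xs_photo[::2], xs_incoh=m.xs_incoh[::2],
            xs_coh=m.xs_coh[::2])
        skipped = m.xs_energy[1:-1:2]
        rel = np.abs(coarse.mass_atten(skipped) / m.mass_atten(skipped) - 1)
        assert rel.max() < 0.01


class TestTableInvariants:
    def test_partials_sum_to_total(self, catalog):
        for m in catalog:
            parts = m.xs_photo + m.xs_incoh + m.xs_coh
            if m.name == "Vacuum":
                assert np.all(parts == 0)
                continue
            np.testing.assert_allclose(parts, m.xs_total, rtol=0.01)

    def test_energies_strictly_increasing(self, catalog):
        for m in catalog:
            assert np.all(np.diff(m.xs_energy) > 0)


class TestRamp:
    def test_partition_validation(self):
        with pytest.raises(ValueError):
            MaterialRamp(((0.0, 0.1, "Air"), (0.2, np.inf, "Water")))
        with pytest.raises(ValueError):
            MaterialRamp(((0.1, 0.2, "Air"), (0.2, np.inf, "Water")))
        with pytest.raises(ValueError):
            MaterialRamp(((0.0, 0.2, "Air"), (0.2, 0.4, "Water")))

    def test_loaded_ramp_matches_builtin(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame({
            "mu_low": [0.0, 0.1], "mu_high": [0.1, np.inf],
            "material": ["Air", "Water"],
            "mu_mat": [5.18e-4, 0.243], "rho_mat": [1.205e-3, 1.0]})
        p = tmp_path / "ramp.csv"
        df.to_csv(p, index=False)
        ramp = load_ramp(p)
        assert ramp.assign(0.05) == "Air"
        assert ramp.nominals[1] == (0.243, 1.0)

    def test_make_ramp_energy_adapted(self, catalog):
        ramp = make_ramp(["Vacuum", "Air", "Water"], 60.0)
        assert ramp.assign(0.2059) == "Water"
        mu_w = material_mu(catalog["Water"], 60.0)
        # density conversion recovers unit density at the scan energy
        ph = volume_from_mu(np.full((1, 1, 1), mu_w), ramp)
        assert ph.density[0, 0, 0] == pytest.approx(1.0, rel=1e-5)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=0, max_value=5, exclude_max=True))
    def test_assignment_total(self, mu):
        # every non-negative attenuation lands in exactly one interval
        ramp = default_ramp()
        name = ramp.assign(mu)
        low, high = {e[2]: (e[0], e[1]) for e in ramp.entries}[str(name)]
        assert low <= mu < high


class TestWaterAirPhantom:
    def test_default_dimensions(self):
        ph = make_water_air_phantom()
        names = np.asarray(ph.material_names)
        nx, ny, nz = ph.shape
        center = names[ph.material_index[nx // 2, ny // 2, nz // 2]]
        assert center == "Air"
        ix = int((5.0 - ph.origin[0]) / ph.voxel_size[0])
        assert names[ph.material_index[ix, ny // 2, nz // 2]] == "Water"

    def test_degenerate_cavity(self):
        ph = make_water_air_phantom(cavity_diameter=0, cavity_length=0)
        names = np.asarray(ph.material_names)[ph.material_index]
        assert "Air" not in names

    def test_voxel_count_matches_cylinder_volume(self):
        ph = make_water_air_phantom(voxel_size=0.2)
        n_inside = int(np.count_nonzero(ph.density > 0))
        expected = np.pi * 10 ** 2 * 20 / 0.2 ** 3
        assert abs(n_inside / expected - 1) < 0.02

    def test_cavity_too_large(self):
        with pytest.raises(ValueError):
            make_water_air_phantom(cavity_diameter=30)


class TestCatphanLikePhantom:
    def test_eight_inserts_present(self):
        ph = make_catphan_like_phantom(voxel_size=0.25)
        names = set(np.asarray(ph.material_names)[ph.material_index].ravel())
        for n in ("Air", "PMP", "LDPE", "Polystyrene", "Acrylic", "Delrin",
                  "Teflon", "Water"):
            assert n in names
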