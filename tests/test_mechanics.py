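import numpy as np
import pytest

from conftest import straight_fibre
from culmforce.errors import ParameterError
from culmforce.geometry import FibreSet, build_cylindrical_grid
from culmforce.mechanics import (
    AttackSweepProfile,
    ImpactCondition,
    fibre_force_partition,
    find_optimal_attack,
    propagate_forces,
    render_fields,
    surface_load,
    sweep_attack_angles,
)
from culmforce.synthetic_data import generate_stem_geometry


def closed_form_fn(f_i, delta_deg, phi_deg, alpha_deg):
    """Independent oracle: F_N = F_I cos(delta) cos(alpha - 180 - phi)."""
    d = np.deg2rad(delta_deg)
    return f_i * np.cos(d) * np.cos(np.deg2rad(alpha_deg - 180.0 - phi_deg))


class TestImpactCondition:
    def test_wraps_out_of_range_azimuth(self):
        with pytest.warns(UserWarning, match="wrapped"):
            imp = ImpactCondition(attack_azimuth_deg=400.0)
        assert imp.attack_azimuth_deg == pytest.approx(40.0)

    def test_direction_points_toward_axis(self):
        imp = ImpactCondition(attack_azimuth_deg=90.0)
        assert np.allclose(imp.direction, [0.0, -1.0, 0.0], atol=1e-12)

    def test_invalid_pressure(self):
        with pytest.raises(ParameterError):
            ImpactCondition(pressure=0.0)


class TestSurfaceLoad:
    def test_total_load_matches_projected_cylinder(self, default_grid):
        field = surface_load(default_grid, ImpactCondition(pressure=1.0))
        total = np.linalg.norm(field.f_in, axis=-1).sum()
        # p * 2 Ro * L with mm -> m conversion: 1 N/m^2 * 2 * 1.8e-3 m * 15e-3 m
        assert total == pytest.approx(1.0 * 2 * 1.8e-3 * 15e-3, rel=0.01)

    def test_leeward_half_zero(self, default_grid):
        imp = ImpactCondition(attack_azimuth_deg=90.0)
        field = surface_load(default_grid, imp)
        mag = np.linalg.norm(field.f_in[:, -1, :, :], axis=-1)
        alphas = default_grid.alpha_centers_deg()
        # attack from azimuth 90: windward surface is the y > 0 arc
        leeward = (alphas > 182.0) & (alphas < 358.0)
        assert np.all(mag[leeward] == 0.0)

    def test_linearity_in_pressure(self, default_grid):
        f1 = surface_load(default_grid, ImpactCondition(pressure=1.0))
        f2 = surface_load(default_grid, ImpactCondition(pressure=2.0))
        assert np.allclose(f2.f_in, 2.0 * f1.f_in, rtol=1e-12)

    def test_only_surface_layer_loaded(self, default_grid):
        field = surface_load(default_grid, ImpactCondition())
        assert np.all(field.f_in[:, :-1, :, :] == 0.0)


class TestPropagation:
    def test_no_fibres_warp_zero_and_radial(self, no_bundle_params):
        grid = build_cylindrical_grid(generate_stem_geometry(no_bundle_params))
        field, warp = propagate_forces(surface_load(grid, ImpactCondition()), grid)
        assert np.all(warp.values == 0.0)
        # outgoing force is purely radial: no z component, no tangential part
        r_in = -grid.radial_hat()
        mag = np.linalg.norm(field.f_out, axis=-1)
        expected = mag[..., None] * r_in[:, None, None, :]
        assert np.allclose(field.f_out, expected, atol=1e-15)

    def test_all_vertical_fibres_warp_zero(self):
        from tests_support_presets import vertical_preset
        grid = build_cylindrical_grid(generate_stem_geometry(vertical_preset()))
        assert grid.fibre_mask.sum() > 0
        _, warp = propagate_forces(surface_load(grid, ImpactCondition()), grid)
        assert np.allclose(warp.values, 0.0, atol=1e-15)

    def test_conservation_every_voxel(self, default_grid):
        field, _ = propagate_forces(surface_load(default_grid, ImpactCondition()), default_grid)
        m_in = np.linalg.norm(field.f_in, axis=-1)
        m_out = np.linalg.norm(field.f_out, axis=-1)
        loaded = m_in > 0
        assert np.allclose(m_out[loaded], m_in[loaded], rtol=1e-9)
        assert field.conservation_residual <= 1e-9

    def test_single_inclined_fibre_warp_is_half_load(self):
        # one 60-degree fibre crossing a single windward voxel, drifting
        # along the attack travel direction: the out-of-plane deflection at
        # its (alpha, r) cell is |Fin| cos(60 deg) = 0.5 |Fin|
        from culmforce.synthetic_data import FibreCenterline

        attack = 90.5                   # centre of the [90, 91) azimuth bin
        phi = attack - 180.0            # travel-direction azimuth
        r_cell = 1.3 + 10.5 * 0.025     # centre of radial bin 10
        zc = 0.5                        # centre of the single 1 mm slice
        drift = 1.0 / np.tan(np.deg2rad(60.0))
        p = np.deg2rad(phi)
        centre = r_cell * np.array([np.cos(np.deg2rad(attack)), np.sin(np.deg2rad(attack))])
        z = np.array([0.0, zc, 1.0])
        pts = np.column_stack([centre[0] + drift * np.cos(p) * (z - zc),
                               centre[1] + drift * np.sin(p) * (z - zc), z])
        fs = FibreSet([FibreCenterline(pts, phi % 360.0, 60.0)], ["outer"])
        grid = build_cylindrical_grid(fibres=fs, outer_radius=1.8, inner_radius=1.3,
                                      bundle_radius=0.012, length=1.0,
                                      segment=1.0, dz=1.0)
        assert grid.fibre_mask.sum() == 1
        ia, ir, iz = np.argwhere(grid.fibre_mask)[0]
        assert ir == 10
        imp = ImpactCondition(attack_azimuth_deg=attack)
        field, warp = propagate_forces(surface_load(grid, imp), grid)
        col_load = np.linalg.norm(field.f_in[ia, -1, iz])
        assert col_load > 0
        assert abs(warp.values[ia, ir]) == pytest.approx(0.5 * col_load, rel=1e-6)

    def test_vertical_fibre_orthogonal_to_horizontal_load(self):
        fs = FibreSet([straight_fibre(90.0, 0.0, x0=0.0, y0=1.55)], ["outer"])
        grid = build_cylindrical_grid(fibres=fs, outer_radius=1.8, inner_radius=1.3,
                                      bundle_radius=0.07, length=15.0)
        _, warp = propagate_forces(surface_load(grid, ImpactCondition(attack_azimuth_deg=90.0)),
                                   grid)
        assert np.allclose(warp.values, 0.0, atol=1e-15)


class TestFibreForcePartition:
    def test_vertical_fibre_pure_bending(self):
        for alpha in (1.0, 45.0, 180.0, 360.0):
            ff = fibre_force_partition(straight_fibre(90.0, 0.0),
                                       ImpactCondition(attack_azimuth_deg=alpha))
            assert ff.axial == pytest.approx(0.0, abs=1e-12)
            assert ff.bending == pytest.approx(1.0)

    def test_horizontal_fibre_pure_axial(self):
        # incline -> 0 with drift along the travel direction (attack 180
        # travels along +x); the tangent is canonicalized upward so the
        # axial part is positive (stretching)
        ff = fibre_force_partition(straight_fibre(1e-7, 0.0),
                                   ImpactCondition(attack_azimuth_deg=180.0))
        assert ff.axial == pytest.approx(1.0, abs=1e-6)
        assert ff.bending == pytest.approx(0.0, abs=1e-3)

    def test_60_degree_partition(self):
        ff = fibre_force_partition(straight_fibre(60.0, 0.0),
                                   ImpactCondition(attack_azimuth_deg=180.0))
        assert ff.axial == pytest.approx(0.5, abs=1e-9)
        assert ff.bending == pytest.approx(np.sqrt(3) / 2, abs=1e-3)

    @pytest.mark.parametrize("delta", [10.0, 35.0, 60.0, 85.0])
    @pytest.mark.parametrize("phi", [0.0, 77.0, 200.0])
    @pytest.mark.parametrize("alpha", [1.0, 90.0, 213.0, 360.0])
    def test_pythagorean_closure(self, delta, phi, alpha):
        imp = ImpactCondition(attack_azimuth_deg=alpha, fibre_impact_force=1.0)
        ff = fibre_force_partition(straight_fibre(delta, phi), imp)
        assert ff.axial ** 2 + ff.bending ** 2 == pytest.approx(1.0, rel=1e-9)
        assert ff.axial == pytest.approx(closed_form_fn(1.0, delta, phi, alpha), abs=1e-9)


class TestSweep:
    def test_empty_fibreset_rejected(self):
        with pytest.raises(ParameterError):
            sweep_attack_angles(FibreSet([], []))

    def test_all_vertical_profile_constant(self):
        fs = FibreSet([straight_fibre(90.0, 0.0, x0=x) for x in (1.4, 1.5, 1.6)],
                      ["outer"] * 3)
        prof = sweep_attack_angles(fs)
        assert np.allclose(prof.mean_fb_over_fi, 1.0, atol=1e-12)
        assert np.allclose(prof.mean_fn_over_fi, 0.0, atol=1e-12)

    def test_single_fibre_matches_closed_form(self, single_fibre_set):
        prof = sweep_attack_angles(single_fibre_set(80.0, 0.0))
        expected = closed_form_fn(1.0, 80.0, 0.0, prof.alphas_deg)
        assert np.allclose(prof.mean_fn_over_fi, expected, atol=1e-9)
        assert np.allclose(prof.mean_fb_over_fi, np.sqrt(1 - expected ** 2), atol=1e-9)
        peaks = prof.alphas_deg[np.abs(prof.mean_fn_over_fi)
                                >= np.abs(prof.mean_fn_over_fi).max() - 1e-12]
        assert set(peaks) == {180.0, 360.0}

    def test_oracle_equivalence_on_parametric_geometry(self, resistant_geometry):
        fs = FibreSet.from_geometry(resistant_geometry)
        prof = sweep_attack_angles(fs)
        oracle = np.mean([closed_form_fn(1.0, f.incline_deg, f.tilt_azimuth_deg,
                                         prof.alphas_deg)
                          for f in resistant_geometry.fibres], axis=0)
        assert np.allclose(prof.mean_fn_over_fi, oracle, atol=1e-9)

    def test_symmetric_layout_bending_nearly_constant(self):
        from tests_support_presets import symmetric_preset
        geom = generate_stem_geometry(symmetric_preset())
        prof = sweep_attack_angles(FibreSet.from_geometry(geom))
        assert prof.bending_amplitude < 1e-4

    def test_periodicity_via_phase_shift(self, single_fibre_set):
        # profile(alpha) must equal profile(alpha + 360): rotating the fibre
        # by a full turn reproduces the same curves
        a = sweep_attack_angles(single_fibre_set(70.0, 25.0))
        b = sweep_attack_angles(single_fibre_set(70.0, 25.0 + 360.0))
        assert np.allclose(a.mean_fn_over_fi, b.mean_fn_over_fi, atol=1e-12)

    def test_worst_case_axial_grows_as_fibres_tilt(self, single_fibre_set):
        maxima = [np.abs(sweep_attack_angles(single_fibre_set(d, 0.0)).mean_fn_over_fi).max()
                  for d in (90.0, 75.0, 60.0, 45.0, 30.0)]
        assert np.all(np.diff(maxima) > 0)


class TestOptimalAttack:
    def test_constant_profile_tie_break(self):
        prof = AttackSweepProfile(np.arange(1, 361, dtype=float),
                                  np.ones(360), np.zeros(360))
        assert find_optimal_attack(prof) == 1.0

    def test_bending_criterion_single_fibre(self, single_fibre_set):
        prof = sweep_attack_angles(single_fibre_set(80.0, 0.0))
        assert find_optimal_attack(prof, "bending") in (90.0, 270.0)

    def test_axial_criterion_single_fibre(self, single_fibre_set):
        prof = sweep_attack_angles(single_fibre_set(80.0, 0.0))
        assert find_optimal_attack(prof, "axial") == 180.0

    def test_unknown_criterion(self, single_fibre_set):
        prof = sweep_attack_angles(single_fibre_set(80.0, 0.0))
        with pytest.raises(ParameterError):
            find_optimal_attack(prof, "torsion")


class TestRendering:
    def test_renders_zero_and_loaded_fields(self, tmp_path, no_bundle_params):
        grid = build_cylindrical_grid(generate_stem_geometry(no_bundle_params))
        field, warp = propagate_forces(surface_load(grid, ImpactCondition()), grid)
        paths = render_fields(field, warp, tmp_path, grid)
        import os
        assert os.path.getsize(paths["pressure"]) > 0
        assert os.path.getsize(paths["warp"]) > 0

    def test_max_pressure_on_windward_surface(self, default_grid):
        imp = ImpactCondition(attack_azimuth_deg=90.0)
        field, _ = propagate_forces(surface_load(default_grid, imp), default_grid)
        mag = field.pressure_magnitude
        surface = mag[:, -1, :]
        # magnitude is conserved down a column, so the global maximum is
        # attained at (and equals) the windward surface load
        assert surface.max() == pytest.approx(mag.max(), rel=1e-9)
        ia = int(np.argmax(surface.max(axis=1)))
        alpha = default_grid.alpha_centers_deg()[ia]
        assert 2.0 < alpha < 178.0  # windward arc for an attack from azimuth 90
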