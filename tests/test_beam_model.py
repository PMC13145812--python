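"""Fermi-Eyges moments, angular/radial/depth fluence and the classical field."""

import numpy as np
import pytest
from scipy.integrate import quad

from flashdose.beam_model import (
    BeamSource,
    EnergySpectrum,
    angular_fluence,
    angular_spread,
    classical_scalar_field,
    compute_ray_state,
    depth_fluence,
    ordinate_weights,
    radial_spread,
)
from flashdose.materials import WATER, mass_scattering_power
from flashdose.phantom import VoxelGrid
from flashdose.quadrature import EnergyGrid, build_quadrature


class TestSpreadMoments:
    def test_constant_scattering_power_closed_forms(self):
        """theta2 = T z and r2 = T z^3 / 3 in a homogeneous medium."""
        T0 = 3.3e-4
        u = np.linspace(0.0, 100.0, 100001)
        T = np.full_like(u, T0)
        for z in (10.0, 50.0, 100.0):
            assert angular_spread(u, T, z) == pytest.approx(T0 * z, rel=1e-6)
            assert radial_spread(u, T, z) == pytest.approx(T0 * z**3 / 3.0, rel=1e-6)

    def test_zero_depth_identities(self):
        u = np.linspace(0, 10, 11)
        T = np.ones_like(u)
        assert angular_spread(u, T, 0.0, theta_i_sq=0.123) == 0.123
        assert radial_spread(u, T, 0.0, r_i_sq=4.5) == 4.5

    def test_piecewise_profile_against_quadrature_oracle(self):
        """Water/bone slab profile vs adaptive quadrature, 1e-6 relative."""
        def T_of(uu):
            return np.where((uu >= 20) & (uu < 30), 5e-4, 1e-4)

        u = np.linspace(0.0, 80.0, 160001)
        T = T_of(u)
        z = 70.0
        ref_theta = sum(quad(lambda x: float(T_of(np.array([x]))[0]), a, b, limit=200)[0]
                        for a, b in [(0, 20), (20, 30), (30, z)])
        ref_r = sum(quad(lambda x: (z - x) ** 2 * float(T_of(np.array([x]))[0]), a, b,
                         limit=200)[0] for a, b in [(0, 20), (20, 30), (30, z)])
        assert angular_spread(u, T, z) == pytest.approx(ref_theta, rel=1e-5)
        assert radial_spread(u, T, z) == pytest.approx(ref_r, rel=1e-5)

    def test_entrance_slab_spreads_more_than_deep_slab(self):
        """The (z-u)^2 lever arm favours scatterers near the entrance."""
        u = np.linspace(0.0, 80.0, 8001)
        entrance = np.where(u < 10, 5e-4, 1e-4)
        deep = np.where((u >= 60) & (u < 70), 5e-4, 1e-4)
        z = 80.0
        assert radial_spread(u, entrance, z) > radial_spread(u, deep, z)


class TestAngularFluence:
    def test_forward_value(self):
        th2 = 0.05
        assert angular_fluence(0.0, th2) == pytest.approx(1.0 / (np.pi * th2), rel=1e-12)

    def test_ratio_structure(self):
        th2 = 0.08
        th = 0.3
        ratio = angular_fluence(th, th2) / angular_fluence(0.0, th2)
        assert ratio == pytest.approx(np.exp(-th**2 / th2) / np.cos(th), rel=1e-12)

    def test_guards(self):
        with pytest.raises(ValueError):
            angular_fluence(np.pi / 2, 0.1)
        with pytest.raises(ValueError):
            angular_fluence(0.1, 0.0)

    def test_delta_limit_goes_to_forward_ordinate(self):
        quad30 = build_quadrature(30.0)
        w = ordinate_weights(quad30, np.array([0.0, 0.0, 1.0]), 0.0)
        assert w.sum() == pytest.approx(1.0)
        assert w[np.argmax(quad30.xi)] == pytest.approx(1.0)

    def test_discretized_weights_vs_monte_carlo_binning(self, quad30):
        """Ordinate weights vs 1e6 Gaussian draws binned to nearest ordinate."""
        axis = np.array([0.0, 0.0, 1.0])
        th2 = 0.18  # typical mid-depth spread in water
        w = ordinate_weights(quad30, axis, th2)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        rng = np.random.default_rng(12345)
        n = 1_000_000
        # 2-D projected angles: each component has variance theta2/2
        tx = rng.normal(0.0, np.sqrt(th2 / 2), n)
        ty = rng.normal(0.0, np.sqrt(th2 / 2), n)
        theta = np.hypot(tx, ty)
        phi = np.arctan2(ty, tx)
        dirs = np.stack([np.sin(theta) * np.cos(phi),
                         np.sin(theta) * np.sin(phi),
                         np.cos(theta)], axis=1)
        nearest = np.argmax(dirs @ quad30.directions.T, axis=1)
        # importance weights convert the planar-Gaussian sampling density to
        # the scalar angular fluence (1/cos planar-to-scalar factor, and the
        # plane-to-sphere Jacobian theta/sin(theta) of the sampling map)
        imp = (1.0 / np.cos(theta)) * np.sin(theta) / np.maximum(theta, 1e-12)
        mc = np.bincount(nearest, weights=imp, minlength=quad30.n) / imp.sum()
        assert np.max(np.abs(mc - w)) < 0.01
        assert np.argmax(mc) == np.argmax(w)


class TestDepthFluence:
    def test_surface_unity(self):
        assert depth_fluence(0.0, 80.0) == pytest.approx(1.0)

    def test_printed_parameterisation_at_range(self):
        """b=2, c=0.1: phi = exp(-2 (z/R)^2)(1 + 0.1 sqrt(z)) checked at z=R."""
        R = 84.0
        expected = np.exp(-2.0) * (1.0 + 0.1 * np.sqrt(R))
        assert depth_fluence(R, R, b=2.0, c=0.1) == pytest.approx(expected, rel=1e-12)

    def test_pure_transmission_monotone(self):
        z = np.linspace(0, 120, 200)
        phi = depth_fluence(z, 80.0, b=2.0, c=0.0)
        assert np.all(np.diff(phi) <= 0)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            depth_fluence(10.0, 0.0)


class TestEnergySpectrum:
    def test_weights_normalised_and_truncated(self):
        spec = EnergySpectrum()
        E, w = spec.components(7)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)
        assert E.min() >= 17.0 and E.max() <= 18.0

    def test_solver_projection(self):
        spec = EnergySpectrum()
        egrid = EnergyGrid.default()
        w = spec.solver_weights(egrid)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w[:16] == 0)  # nothing below 17 MeV


class TestRayState:
    def test_moment_integration_against_oracle(self, stopping_table):
        """Segment-wise moments vs fine independent integration in water."""
        grid = VoxelGrid.uniform((10, 10, 120), spacing=1.0)
        st = compute_ray_state(grid, np.array([5.0, 5.0, -10.0]),
                               np.array([0.0, 0.0, 1.0]), 17.5, stopping_table)
        # independent fine-step integration of the same physics
        dz = 0.005
        zz = np.arange(dz / 2, 80.0, dz)
        E = 17.5
        th2 = 0.0
        m0 = m1 = m2 = 0.0
        for z in zz:
            T = mass_scattering_power(WATER, max(E, 0.2)) * 0.1
            th2 += T * dz
            m0 += T * dz
            m1 += T * dz * z
            m2 += T * dz * z**2
            E = max(E - dz * float(stopping_table.linear_mm(E)), 0.0)
        z_eval = 80.0
        r2_oracle = z_eval**2 * m0 - 2 * z_eval * m1 + m2
        assert st.interp(np.array([z_eval]), "theta_sq")[0] == pytest.approx(th2, rel=0.01)
        assert st.interp(np.array([z_eval]), "r_sq_add")[0] == pytest.approx(r2_oracle, rel=0.01)
        assert st.interp(np.array([z_eval]), "E")[0] == pytest.approx(E, abs=0.1)

    def test_spreads_non_decreasing_and_phi_z_positive(self, stopping_table):
        grid = VoxelGrid.uniform((10, 10, 100), spacing=1.0)
        st = compute_ray_state(grid, np.array([5.0, 5.0, -1.0]),
                               np.array([0.0, 0.0, 1.0]), 17.5, stopping_table)
        assert np.all(np.diff(st.theta_sq) >= 0)
        assert np.all(np.diff(st.r_sq_add) >= 0)
        assert np.all(st.phi_z >= 0)
        assert st.interp(np.array([0.0]), "phi_z")[0] == pytest.approx(1.0, abs=1e-3)


class TestClassicalField:
    def test_lateral_moment_matches_prediction(self, stopping_table):
        """Mid-depth per-axis variance within 2% of the moment prediction."""
        grid = VoxelGrid.uniform((90, 90, 50), spacing=1.0)
        beam = BeamSource(gantry_deg=0.0, couch_deg=0.0,
                          isocenter=np.array([45.0, 45.0, 0.0]))
        res = classical_scalar_field(beam, grid, table=stopping_table, n_sub=1)
        st = res["states"][0]
        flu = np.asarray(res["fluence"], float)
        u, v = beam.bev_basis()
        z_idx = 30
        z = grid.centers(2)[z_idx]
        sl = flu[:, :, z_idx]
        x = grid.centers(0) - beam.isocenter[0]
        y = grid.centers(1) - beam.isocenter[1]
        wx = sl.sum(axis=1)
        wy = sl.sum(axis=0)
        var_grid_x = (wx * x**2).sum() / wx.sum() - ((wx * x).sum() / wx.sum()) ** 2
        var_grid_y = (wy * y**2).sum() / wy.sum() - ((wy * y).sum() / wy.sum()) ** 2
        r2a = st.interp(np.array([z]), "r_sq_add")[0]
        # map sigma_x/sigma_y (BEV u/v axes) onto the grid axes
        sig_on_x = beam.sigma_x if abs(u[0]) > 0.5 else beam.sigma_y
        sig_on_y = beam.sigma_x if abs(u[1]) > 0.5 else beam.sigma_y
        assert var_grid_x == pytest.approx(sig_on_x**2 + r2a / 2.0, rel=0.02)
        assert var_grid_y == pytest.approx(sig_on_y**2 + r2a / 2.0, rel=0.02)

    def test_incident_plane_integral_matches_spot_weight(self, watertank_case):
        """Total incident weight is conserved (MU bookkeeping)."""
        grid = watertank_case["grid"]
        flu = np.asarray(watertank_case["fine"]["fluence"], float)
        st = watertank_case["fine"]["states"][0]
        plane = flu[:, :, 0].sum() * grid.spacing[0] * grid.spacing[1]
        # the first slice sits at 0.5 mm depth where phi_z already has buildup
        phi_z0 = st.interp(np.array([grid.centers(2)[0]]), "phi_z")[0]
        assert plane == pytest.approx(phi_z0, rel=0.02)

    def test_solver_projection_consistent_with_scalar(self, watertank_case, quad30, egrid):
        """Summing the ordinate/energy-resolved field recovers the scalar one."""
        phi = watertank_case["phi_classical"]
        coarse = watertank_case["coarse"]
        beam = watertank_case["beam"]
        scalar = phi.sum(axis=(0, 1))
        ref = classical_scalar_field(beam, coarse,
                                     S_field=watertank_case["fine"]["S_field"])["fluence"]
        assert np.all(phi >= 0)
        sel = ref > ref.max() * 1e-3
        assert np.allclose(scalar[sel], ref[sel], rtol=5e-3, atol=ref.max() * 1e-5)

    def test_fluence_nonnegative(self, watertank_case):
        assert np.all(watertank_case["phi_classical"] >= 0)
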