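"""Energy selection, the empirical depth-dose surrogate, spot placement,
the multiplicative optimizer and DVH/plan statistics."""

import numpy as np
import pytest

from flashdose.beam_model import BeamSource
from flashdose.phantom import VoxelGrid
from flashdose.planner import (
    EmpiricalDepthDoseParams,
    PlanObjective,
    SurrogateEngine,
    dvh,
    empirical_depth_dose,
    optimize_weights,
    place_spots,
    plan_statistics,
    prescription_scale,
    ratio_update,
    select_energy,
)


class TestSelectEnergy:
    def test_range_energy_rule(self):
        assert select_energy(40.0) == pytest.approx(16.0)

    def test_rounding_to_half_mev(self):
        assert select_energy(33.0) == pytest.approx(13.0)
        assert select_energy(34.0) == pytest.approx(13.5)

    def test_too_deep_rejected(self):
        with pytest.raises(ValueError, match="too deep"):
            select_energy(50.0)

    def test_shallow_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert select_energy(0.1) == 1.0

    def test_monotone_in_depth(self):
        depths = np.linspace(5.0, 43.0, 50)
        energies = [select_energy(d) for d in depths]
        assert all(b >= a for a, b in zip(energies, energies[1:]))


class TestEmpiricalDepthDose:
    def test_zero_at_surface(self):
        p = EmpiricalDepthDoseParams(e=14.0)
        assert empirical_depth_dose(0.0, p) == 0.0

    def test_vanishes_at_large_depth(self):
        p = EmpiricalDepthDoseParams(e=14.0)
        assert empirical_depth_dose(1e4, p) < 1e-4

    def test_pointwise_against_independent_arithmetic(self):
        """e = 14 MeV at z in {10, 35, 50} mm, written out independently."""
        e = 14.0
        N, mu, t = 15.0, 0.001, 0.0
        n, R50 = 4000.0 * e, 2.5 * e
        p = EmpiricalDepthDoseParams(e=e)
        for z in (10.0, 35.0, 50.0):
            expected = (z**0.1 / (N + z**0.2)) * np.exp(-mu * z) * (
                1.0 - (z - R50) / np.sqrt(n**0.5 + (z - R50) ** 2) + t)
            assert empirical_depth_dose(z, p) == pytest.approx(expected, rel=1e-12)

    def test_derived_parameters(self):
        p = EmpiricalDepthDoseParams(e=16.0)
        assert p.n == pytest.approx(4000.0 * 16.0)
        assert p.R_50 == pytest.approx(2.5 * 16.0)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            empirical_depth_dose(-1.0, EmpiricalDepthDoseParams(e=14.0))


class TestPlaceSpots:
    def test_sphere_count_matches_enumeration_oracle(self, head_case):
        grid = head_case.grid
        gtv = head_case.masks["gtv"]
        iso = grid.origin + (np.argwhere(gtv).mean(axis=0) + 0.5) * grid.spacing
        beam = BeamSource(gantry_deg=240.0, couch_deg=0.0, isocenter=iso)
        sm = place_spots(gtv, grid, beam, spacing_mm=4.0, margin_mm=4.0)
        # brute-force oracle over the candidate lattice
        u, v = beam.bev_basis()
        pts = grid.origin + (np.argwhere(gtv) + 0.5) * grid.spacing
        rel = pts - iso
        proj = np.stack([rel @ u, rel @ v], axis=1)
        count = 0
        for gx in np.arange(-40, 41, 4.0):
            for gy in np.arange(-40, 41, 4.0):
                if np.min(np.hypot(proj[:, 0] - gx, proj[:, 1] - gy)) <= 4.0 + 1e-9:
                    count += 1
        assert len(sm) == count

    def test_point_target_single_spot(self):
        grid = VoxelGrid.uniform((21, 21, 21), spacing=1.0)
        gtv = np.zeros(grid.shape, bool)
        gtv[10, 10, 10] = True
        iso = grid.origin + (np.array([10, 10, 10]) + 0.5) * grid.spacing
        beam = BeamSource(gantry_deg=0.0, couch_deg=0.0, isocenter=iso)
        sm = place_spots(gtv, grid, beam, spacing_mm=4.0, margin_mm=0.0)
        assert len(sm) == 1

    def test_lattice_translation_consistency(self):
        grid = VoxelGrid.uniform((41, 41, 21), spacing=1.0)
        beam_iso = grid.origin + np.array([20.5, 20.5, 10.5])
        beam = BeamSource(gantry_deg=0.0, couch_deg=0.0, isocenter=beam_iso)
        gtv1 = np.zeros(grid.shape, bool)
        gtv1[16:25, 16:25, 9:12] = True
        gtv2 = np.zeros(grid.shape, bool)
        gtv2[12:21, 16:25, 9:12] = True  # shifted exactly 4 mm along x
        s1 = place_spots(gtv1, grid, beam)
        s2 = place_spots(gtv2, grid, beam)
        assert len(s1) == len(s2)

    def test_empty_gtv_rejected(self):
        grid = VoxelGrid.uniform((5, 5, 5))
        beam = BeamSource(isocenter=np.array([2.5, 2.5, 2.5]))
        with pytest.raises(ValueError):
            place_spots(np.zeros(grid.shape, bool), grid, beam)


class TestOptimizer:
    def test_single_spot_analytic_weight(self):
        """One spot, one voxel at achievable dose: w -> target / unit dose."""
        I = np.array([[0.8]])
        target = np.array([12.0])
        w = np.array([1.0])
        for _ in range(50):
            w = ratio_update(I, w, target, I.T @ w, 1.0)
        assert w[0] == pytest.approx(12.0 / 0.8, rel=1e-3)

    def test_two_decoupled_spots(self):
        I = np.array([[0.5, 0.0], [0.0, 1.5]])
        target = np.array([10.0, 3.0])
        w = np.ones(2)
        for _ in range(60):
            w = ratio_update(I, w, target, I.T @ w, 1.0)
        assert np.allclose(w, [20.0, 2.0], rtol=1e-3)

    def test_random_weight_recovery_on_head_fixture(self, head_case):
        """Dose generated from random weights is re-optimised from a uniform
        start; the weights are recovered within 5% RMS."""
        grid = head_case.grid
        gtv = head_case.masks["gtv"]
        iso = grid.origin + (np.argwhere(gtv).mean(axis=0) + 0.5) * grid.spacing
        beam = BeamSource(gantry_deg=240.0, couch_deg=0.0, isocenter=iso)
        sm = place_spots(gtv, grid, beam)
        eng = SurrogateEngine(head_case, beam, sm, 14.0)
        rng = np.random.default_rng(2)
        w_true = 0.5 + rng.random(len(sm))
        dose_field = eng.dose_field(w_true)
        idx = np.argwhere(dose_field > 1e-3 * dose_field.max())
        idx = idx[rng.choice(len(idx), min(8000, len(idx)), replace=False)]
        pts = grid.origin + (idx + 0.5) * grid.spacing
        infl = eng.influence(pts)
        target = infl.T @ w_true
        w = np.ones(len(sm))
        for _ in range(3000):
            w = ratio_update(infl, w, target, infl.T @ w, 1.0)
        rms = np.sqrt(np.mean((w - w_true) ** 2)) / np.mean(w_true)
        assert rms < 0.05

    def test_objective_mostly_monotone(self, head_case):
        """The objective decreases in at least 95% of iterations."""
        grid = head_case.grid
        gtv = head_case.masks["gtv"]
        iso = grid.origin + (np.argwhere(gtv).mean(axis=0) + 0.5) * grid.spacing
        engines = []
        for g in (240.0, 300.0):
            beam = BeamSource(gantry_deg=g, couch_deg=0.0, isocenter=iso)
            sm = place_spots(gtv, grid, beam)
            engines.append(SurrogateEngine(head_case, beam, sm, 14.0))
        objectives = [PlanObjective("gtv", "rms_around_dose", 30.0, 100.0),
                      PlanObjective("brain", "volume_at_dose", 12.0, 1.0),
                      PlanObjective("skin", "max_dose", 25.5, 1.0)]
        _, report = optimize_weights(engines, objectives, head_case.masks,
                                     n_iter=80, rng=np.random.default_rng(0))
        h = np.array(report["objective_history"])
        decreasing = np.sum(np.diff(h) <= 1e-9 * h[0])
        assert decreasing >= 0.95 * (len(h) - 1)

    def test_requires_objective(self, head_case):
        with pytest.raises(ValueError):
            optimize_weights([], [], head_case.masks)

    def test_unknown_structure_rejected(self, head_case):
        with pytest.raises(ValueError, match="unknown structure"):
            optimize_weights([], [PlanObjective("liver", "max_dose", 1.0)],
                             head_case.masks)


class TestPrescriptionScale:
    def test_exact_d98_after_rescale(self):
        rng = np.random.default_rng(0)
        gtv_dose = 15.0 + rng.random(5000) * 10.0
        k = prescription_scale(gtv_dose, 21.0)
        scaled = k * gtv_dose
        assert float(np.quantile(scaled, 0.02)) == pytest.approx(21.0, abs=1e-9)

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            prescription_scale(np.zeros(10))


class TestPlanStatistics:
    def test_uniform_gtv_degenerate(self):
        dose = np.zeros((20, 20, 20))
        gtv = np.zeros_like(dose, bool)
        gtv[8:12, 8:12, 8:12] = True
        dose[gtv] = 21.0
        stats = plan_statistics(dose, {"gtv": gtv}, voxel_volume_cm3=1e-3)
        s = stats["structures"]["gtv"]
        assert s["D98_Gy"] == pytest.approx(21.0, abs=0.05)
        assert s["D2_Gy"] == pytest.approx(21.0, abs=0.05)
        assert stats["CI@21.0Gy"] == pytest.approx(1.0)

    def test_two_level_dvh(self):
        dose = np.zeros((10, 10, 2))
        gtv = np.ones_like(dose, bool)
        dose[:5] = 30.0
        dose[5:] = 10.0
        stats = plan_statistics(dose, {"gtv": gtv}, voxel_volume_cm3=1e-3)
        s = stats["structures"]["gtv"]
        assert s["D98_Gy"] == pytest.approx(10.0, abs=0.1)
        assert s["D2_Gy"] == pytest.approx(30.0, abs=0.1)

    def test_sphere_isodose_ci_matches_analytic(self):
        """Radially decreasing dose: CI equals the analytic volume ratio."""
        grid = VoxelGrid.uniform((60, 60, 60), spacing=1.0)
        X, Y, Z = grid.center_mesh()
        r = np.sqrt((X - 30) ** 2 + (Y - 30) ** 2 + (Z - 30) ** 2)
        dose = 42.0 * np.exp(-r / 20.0)
        gtv = r <= 10.0
        vox = 1e-3
        stats = plan_statistics(dose, {"gtv": gtv}, vox, ci_levels_Gy=(21.0,))
        r_iso = -20.0 * np.log(21.0 / 42.0)  # analytic 21 Gy isodose radius
        analytic_ci = (r_iso / 10.0) ** 3
        assert stats["CI@21.0Gy"] == pytest.approx(analytic_ci, rel=0.03)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            plan_statistics(np.ones((4, 4, 4)), {"gtv": np.zeros((4, 4, 4), bool)}, 1e-3)

    def test_dvh_basic_properties(self):
        dose = np.linspace(0, 10, 1000).reshape(10, 10, 10)
        edges, frac = dvh(dose, np.ones((10, 10, 10), bool))
        assert frac[0] == 1.0
        assert frac[-1] >= 0.0
        assert np.all(np.diff(frac) <= 1e-12)
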