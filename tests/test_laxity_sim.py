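import numpy as np
import pytest
from scipy.optimize import brentq

from aclrsim import fixtures as fx
from aclrsim import laxity_sim as lx
from aclrsim.errors import ConfigurationError, InvalidParameterError
from aclrsim.graft_meshing import GraftSpec
from aclrsim.ligament_mechanics import blankevoort_force, strain_at_force


def _ap_only_step(force_y, substeps=3):
    return lx.ProtocolStep(
        prescribed={n: 0.0 for n in lx.DOF_NAMES if n != "anterior_posterior"},
        force=np.array([0.0, force_y, 0.0]),
        ramp_substeps=substeps,
    )


class TestEquilibriumSolver:
    def test_one_dof_closed_form(self):
        """Antagonist-pair knee matches d = -F L0 / (2k) to 1e-6 relative."""
        model, info = fx.make_antagonist_pair_knee()
        for F in (20.0, 100.0, info["max_linear_force"]):
            res = lx.solve_equilibrium(model, _ap_only_step(-F))
            assert res.pose.anterior_posterior == pytest.approx(
                -F * info["compliance"], rel=1e-6
            )
            assert res.residual_force < 1e-6

    def test_doubling_stiffness_halves_displacement(self):
        m1, info1 = fx.make_antagonist_pair_knee(k=8000.0)
        m2, _ = fx.make_antagonist_pair_knee(k=16000.0)
        d1 = lx.solve_equilibrium(m1, _ap_only_step(-50.0)).pose.anterior_posterior
        d2 = lx.solve_equilibrium(m2, _ap_only_step(-50.0)).pose.anterior_posterior
        assert d1 == pytest.approx(2 * d2, rel=1e-9)

    def test_zero_load_zero_displacement(self):
        model, _ = fx.make_antagonist_pair_knee()
        res = lx.solve_equilibrium(model, _ap_only_step(0.0))
        assert abs(res.pose.anterior_posterior) < 1e-9

    def test_converged_residual_below_tolerance(self, toy_knee):
        res = lx.run_lachman(toy_knee)
        assert res.converged
        assert res.residual_force < 1e-6
        assert res.residual_moment < 1e-6

    def test_symmetric_knee_decouples_lateral_dofs(self):
        """With equal collaterals the toy knee is mirror-symmetric: an AP
        load produces no ML translation and no adduction."""
        knee = fx.make_toy_knee(laws={"LCL": {"k": 7496.0, "eps_r": 0.04}})
        res = lx.run_lachman(knee)
        assert abs(res.pose.medial_lateral) < 1e-8
        assert abs(res.pose.adduction) < 1e-8
        assert abs(res.pose.external_rotation) < 1e-12  # prescribed

    def test_unknown_dof_rejected(self):
        with pytest.raises(ConfigurationError):
            lx.ProtocolStep(prescribed={"varus": 1.0})


class TestDrawer:
    def test_zero_force_zero_relative_displacement(self, toy_knee):
        res = lx.run_drawer(toy_knee, 30.0, 0.0)
        assert abs(res.relative_ap_displacement) < 1e-9

    def test_sign_flip_on_symmetric_cruciates(self):
        knee = fx.make_toy_knee(
            laws={
                "ACL": {"k": 12000.0, "eps_r": 0.05},
                "PCL": {"k": 12000.0, "eps_r": 0.05},
                "LCL": {"k": 7496.0, "eps_r": 0.04},
            }
        )
        fwd = lx.run_drawer(knee, 0.0, 100.0).relative_ap_displacement
        back = lx.run_drawer(knee, 0.0, -100.0).relative_ap_displacement
        assert fwd == pytest.approx(-back, rel=1e-6)

    def test_posterior_drawer_loads_acl_anterior_loads_pcl(self, toy_knee):
        post = lx.run_drawer(toy_knee, 30.0, -100.0)
        ant = lx.run_drawer(toy_knee, 30.0, 100.0)
        assert post.total_tension("ACL") > post.total_tension("PCL")
        assert ant.total_tension("PCL") > ant.total_tension("ACL")

    def test_lachman_is_posterior(self, toy_knee):
        res = lx.run_lachman(toy_knee)
        assert res.relative_ap_displacement < 0


class TestPretension:
    def test_zero_pretension_sets_slack_at_current_length(self, aclr_builder):
        m = aclr_builder()
        lx.apply_pretension(m, 0.0, fixation_angle=20.0)
        g = m.grafts[0]
        T = m.femur_transform(g.fixation_pose)
        assert np.allclose(g.bundle.current_lengths(T), g.bundle.L_0)
        assert g.bundle.tensions(T).sum() == pytest.approx(0.0, abs=1e-9)

    def test_branch_junction_pretension(self):
        """F = k eps_l lands exactly on the toe/linear junction strain."""
        k, eps_l = 17844.0, 0.03
        assert strain_at_force(k * eps_l, k, eps_l) == pytest.approx(2 * eps_l, rel=1e-12)

    def test_toe_inverse_matches_root_finder(self):
        k, eps_l = 17844.0, 0.03
        for F in (1.0, 80.0, 500.0, k * eps_l * 0.999):
            closed = strain_at_force(F, k, eps_l)
            num = brentq(lambda e: blankevoort_force(e, k, eps_l) - F, 0, 1, xtol=1e-15)
            assert closed == pytest.approx(num, abs=1e-9)

    def test_self_consistency_at_fixation_pose(self, aclr_builder):
        m = aclr_builder()
        lx.apply_pretension(m, 80.0, fixation_angle=20.0)
        g = m.grafts[0]
        T = m.femur_transform(g.fixation_pose)
        assert g.bundle.tensions(T).sum() == pytest.approx(80.0, abs=1e-6)

    def test_negative_pretension_rejected(self, aclr_builder):
        with pytest.raises(InvalidParameterError):
            lx.apply_pretension(aclr_builder(), -5.0)

    def test_lachman_requires_pretension_on_aclr(self, aclr_builder):
        with pytest.raises(InvalidParameterError):
            lx.run_lachman(aclr_builder())


class TestGraftEffectiveBundle:
    def test_stiffness_from_area_and_modulus(self):
        spec = GraftSpec(radius=4.0, n_bundles=1, material="semitendinosus")
        b = lx.graft_effective_bundle(spec, [(0, 0, 0)], [(0, 30, 0)])
        assert b.law.k == pytest.approx(362.0 * np.pi * 16.0)

    def test_doubling_radius_quadruples_stiffness(self):
        k = [
            lx.graft_effective_bundle(
                GraftSpec(radius=r, n_bundles=1), [(0, 0, 0)], [(0, 30, 0)]
            ).law.k
            for r in (2.0, 4.0)
        ]
        assert k[1] == pytest.approx(4 * k[0], rel=1e-12)

    def test_db_area_conservation(self):
        """Two R=2.5 bundles carry the same area as one R = 2.5 sqrt(2)."""
        single = GraftSpec(radius=lx.equal_area_radius([2.5, 2.5]), n_bundles=1)
        assert single.section_area == pytest.approx(2 * np.pi * 2.5**2, rel=1e-12)

    def test_unknown_material_rejected(self):
        with pytest.raises(ConfigurationError):
            lx.graft_effective_bundle(
                GraftSpec(radius=4.0, material="fascia lata"), [(0, 0, 0)], [(0, 30, 0)]
            )


class TestDisplacementDifference:
    def test_examples(self, rm_lachman):
        assert lx.displacement_difference(rm_lachman, rm_lachman) == 0.0
        a = lx.SimResult(rm_lachman.pose, 10.2, {}, 0, 0, 0, 0, True)
        b = lx.SimResult(rm_lachman.pose, 10.0, {}, 0, 0, 0, 0, True)
        assert lx.displacement_difference(a, b) == pytest.approx(0.2)
        assert lx.displacement_difference(b, a) == pytest.approx(0.2)


class TestSensitivityGrid:
    def test_default_grid_has_91_combinations(self):
        ms, mp = lx.multiplier_grid()
        assert len(ms) == 13 and len(mp) == 7
        assert len(ms) * len(mp) == 91

    def test_zero_span_single_combination(self, toy_knee):
        curve = np.array([[30.0, -100.0, -1.0]])
        grid = lx.sensitivity_grid(toy_knee, curve, stiffness_span=0, prestrain_span=0)
        assert grid.n_combinations == 1 and len(grid.records) == 1

    def test_noise_free_recovery(self, toy_knee):
        curve = fx.make_synthetic_laxity_curve(
            toy_knee, noise_sd=0.0, multipliers=(0.9, 1.05)
        )
        grid = lx.sensitivity_grid(toy_knee, curve)
        best = grid.best
        assert best["stiffness_multiplier"] == pytest.approx(0.9)
        assert best["prestrain_multiplier"] == pytest.approx(1.05)
        assert best["mse"] < 1e-12

    def test_empty_experiments_rejected(self, toy_knee):
        with pytest.raises(InvalidParameterError):
            lx.sensitivity_grid(toy_knee, np.empty((0, 3)))

    def test_tie_break_prefers_multipliers_near_one(self):
        grid = lx.SensitivityGrid(
            np.array([0.9, 1.0]),
            np.array([1.0]),
            [
                {"stiffness_multiplier": 0.9, "prestrain_multiplier": 1.0, "mse": 0.5},
                {"stiffness_multiplier": 1.0, "prestrain_multiplier": 1.0, "mse": 0.5},
            ],
        )
        assert grid.best["stiffness_multiplier"] == 1.0


class TestWhatIfTrends:
    def test_radius_and_pretension_monotone(self, rm_lachman, aclr_builder):
        rows = lx.sweep_what_if(rm_lachman, aclr_builder, radii=[2.0, 3.0, 4.0, 5.0])
        laxity = [abs(r["displacement"]) for r in rows]
        assert all(a > b for a, b in zip(laxity, laxity[1:]))
        rows = lx.sweep_what_if(rm_lachman, aclr_builder, pretensions=[40.0, 80.0, 120.0])
        laxity = [abs(r["displacement"]) for r in rows]
        assert all(a > b for a, b in zip(laxity, laxity[1:]))

    def test_stress_proxy_rises_with_pretension_and_falls_with_radius(
        self, rm_lachman, aclr_builder
    ):
        rows = lx.sweep_what_if(rm_lachman, aclr_builder, pretensions=[40.0, 120.0])
        assert rows[1]["stress_proxy"] > rows[0]["stress_proxy"]
        rows = lx.sweep_what_if(rm_lachman, aclr_builder, radii=[2.5, 5.0])
        assert rows[1]["stress_proxy"] < rows[0]["stress_proxy"]

    def test_fixation_above_30_increases_laxity(self, rm_lachman, aclr_builder):
        rows = lx.sweep_what_if(
            rm_lachman, aclr_builder, fixation_angles=[30.0, 40.0, 50.0]
        )
        laxity = [abs(r["displacement"]) for r in rows]
        assert laxity[0] < laxity[1] < laxity[2]

    def test_sb_vs_db_comparable_at_matched_area(self, rm_lachman, aclr_builder):
        """Equal total section area and total pretension: the two techniques
        restrain the knee to within a factor 2 of each other."""
        sb = lx.sweep_what_if(
            rm_lachman, aclr_builder, techniques=["SB"],
            radii=[lx.equal_area_radius([2.5, 2.5])], pretensions=[80.0],
        )[0]
        db = lx.sweep_what_if(
            rm_lachman, aclr_builder, techniques=["DB"], radii=[2.5], pretensions=[40.0]
        )[0]
        lo, hi = sorted([sb["difference"], db["difference"]])
        assert hi <= 2 * max(lo, 1e-6)
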