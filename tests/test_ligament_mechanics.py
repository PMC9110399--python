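import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from aclrsim import ligament_mechanics as lm
from aclrsim.errors import InvalidParameterError, NumericalDegeneracyError


class TestBlankevoortForce:
    @pytest.mark.parametrize(
        "eps,k,eps_l,expected",
        [
            (-0.01, 10000, 0.03, 0.0),  # slack springs carry no load
            (-0.5, 10000, 0.03, 0.0),
            (0.10, 10000, 0.03, 700.0),  # linear branch k (eps - eps_l)
            (0.06, 12759, 0.03, 12759 * 0.03),  # branch junction value
        ],
    )
    def test_values(self, eps, k, eps_l, expected):
        assert lm.blankevoort_force(eps, k, eps_l) == pytest.approx(expected, abs=1e-9)

    def test_branch_continuity_c0_c1(self):
        """Both branches meet at eps = 2 eps_l with value k eps_l and slope k."""
        k, eps_l = 12759.0, 0.03
        j = 2 * eps_l
        toe = 0.25 * k * j**2 / eps_l
        lin = k * (j - eps_l)
        assert abs(toe - lin) / lin < 1e-12
        h = 1e-8
        slope_toe = (lm.blankevoort_force(j, k, eps_l) - lm.blankevoort_force(j - h, k, eps_l)) / h
        slope_lin = (lm.blankevoort_force(j + h, k, eps_l) - lm.blankevoort_force(j, k, eps_l)) / h
        assert slope_toe == pytest.approx(k, rel=1e-6)
        assert slope_lin == pytest.approx(k, rel=1e-6)

    @settings(max_examples=60, derandomize=True)
    @given(
        k=st.floats(10.0, 5e4),
        eps_l=st.floats(0.005, 0.1),
        a=st.floats(-0.2, 0.5),
        b=st.floats(-0.2, 0.5),
    )
    def test_non_decreasing(self, k, eps_l, a, b):
        lo, hi = min(a, b), max(a, b)
        assert lm.blankevoort_force(lo, k, eps_l) <= lm.blankevoort_force(hi, k, eps_l) + 1e-12

    def test_closed_form_inverse_matches_root_finder(self):
        k, eps_l = 17844.0, 0.03
        for F in (5.0, 80.0, k * eps_l, 900.0, 2500.0):
            eps_cf = lm.strain_at_force(F, k, eps_l)
            eps_num = brentq(
                lambda e: lm.blankevoort_force(e, k, eps_l) - F, 0.0, 1.0, xtol=1e-14
            )
            assert eps_cf == pytest.approx(eps_num, abs=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            lm.blankevoort_force(0.1, -1.0, 0.03)
        with pytest.raises(InvalidParameterError):
            lm.blankevoort_force(0.1, 100.0, 0.0)


class TestLengthsAndStrains:
    @pytest.mark.parametrize(
        "L_r,eps_r,expected", [(30, 0, 30.0), (30, 0.05, 28.571428571428573)]
    )
    def test_slack_length(self, L_r, eps_r, expected):
        assert lm.slack_length(L_r, eps_r) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(L_r=st.floats(1.0, 100.0), eps_r=st.floats(-0.5, 0.5))
    def test_reference_strain_round_trip(self, L_r, eps_r):
        """A spring at length L_r has strain exactly eps_r by construction."""
        L0 = lm.slack_length(L_r, eps_r)
        assert lm.spring_strain(L_r, L0) == pytest.approx(eps_r, abs=1e-12)

    def test_spring_strain_values(self):
        assert lm.spring_strain(30.0, 30.0) == 0.0
        assert lm.spring_strain(31.5, 30.0) == pytest.approx(0.05)
        eps = lm.spring_strain(15.0, 30.0)
        assert eps == pytest.approx(-0.5)
        assert lm.blankevoort_force(eps, 1000.0) == 0.0

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            lm.slack_length(30.0, -1.0)
        with pytest.raises(InvalidParameterError):
            lm.spring_strain(10.0, 0.0)


class TestStiffness:
    @pytest.mark.parametrize(
        "E,A,expected",
        [(355, 35.94, 12759), (304, 42.12, 12804), (355, 7.2, 2556)],
    )
    def test_reported_stiffness_from_modulus_and_area(self, E, A, expected):
        assert lm.round_for_report(lm.stiffness_from_EA(E, A)) == expected

    def test_full_precision_kept_internally(self):
        assert lm.stiffness_from_EA(355, 35.94) == pytest.approx(12758.7)

    @pytest.mark.parametrize(
        "k,n,per", [(2000, 1, 2000.0), (12759, 10, 1275.9), (2000, 8, 250.0)]
    )
    def test_distribute(self, k, n, per):
        got = lm.distribute_stiffness(k, n)
        assert got == pytest.approx(per)
        assert got * n == pytest.approx(k, rel=1e-12)

    def test_distribute_invalid(self):
        with pytest.raises(InvalidParameterError):
            lm.distribute_stiffness(1000, 0)

    def test_invalid_material(self):
        with pytest.raises(InvalidParameterError):
            lm.stiffness_from_EA(0.0, 10.0)
        with pytest.raises(InvalidParameterError):
            lm.MaterialConstants(E=-1.0, A=10.0)

    def test_meniscal_root_constant(self):
        assert lm.MENISCAL_ROOT_STIFFNESS == 2000.0


def _single_spring_bundle(k=1000.0, eps_r=0.0, origin=(0, 0, 0), insertion=(10, 0, 0)):
    b = lm.LigamentBundle("test", [origin], [insertion], lm.SpringLaw(k=k, eps_r=eps_r))
    return b.resolve_slack_lengths()


class TestBundleForce:
    def test_zero_at_reference_with_zero_prestrain(self):
        b = _single_spring_bundle()
        f, m, t = lm.bundle_force(b)
        assert np.allclose(f, 0) and np.allclose(m, 0) and np.allclose(t, 0)

    def test_single_spring_stretch_along_x(self):
        """Tension equals the scalar law; the force pulls the femur back."""
        b = _single_spring_bundle(k=5000.0, eps_r=0.08)
        T = np.eye(4)
        T[0, 3] = -1.0  # femoral end moved -x: chord 10 -> 11 from L_r 10
        f, m, t = lm.bundle_force(b, T)
        L0 = 10.0 / 1.08
        eps = (11.0 - L0) / L0
        expected = lm.blankevoort_force(eps, 5000.0)
        assert t[0] == pytest.approx(expected, rel=1e-12)
        assert f[0] == pytest.approx(expected, rel=1e-12)  # pull toward +x
        assert abs(f[1]) < 1e-12 and abs(f[2]) < 1e-12

    def test_mirror_symmetric_pair_cancels_lateral_force(self):
        b = lm.LigamentBundle(
            "pair",
            [(0, -5, 0), (0, 5, 0)],
            [(20, -5, 0), (20, 5, 0)],
            lm.SpringLaw(k=2000.0, eps_r=0.05),
        ).resolve_slack_lengths()
        T = np.eye(4)
        T[0, 3] = -2.0
        f, _, t = lm.bundle_force(b, T)
        assert t[0] == pytest.approx(t[1])
        assert abs(f[1]) < 1e-9

    def test_superposition_matches_single_spring_with_total_k(self):
        n = 7
        multi = lm.LigamentBundle(
            "multi",
            [(0, 0, 0)] * n,
            [(10, 0, 0)] * n,
            lm.SpringLaw(k=7000.0, eps_r=0.05),
        ).resolve_slack_lengths()
        single = _single_spring_bundle(k=7000.0, eps_r=0.05)
        T = np.eye(4)
        T[0, 3] = -1.3
        f_multi, _, _ = lm.bundle_force(multi, T)
        f_single, _, _ = lm.bundle_force(single, T)
        assert np.allclose(f_multi, f_single, rtol=1e-12)

    def test_degenerate_chord_raises(self):
        b = _single_spring_bundle()
        T = np.eye(4)
        T[0, 3] = 10.0  # femoral end lands exactly on the insertion
        with pytest.raises(NumericalDegeneracyError):
            lm.bundle_force(b, T)

    def test_unresolved_slack_lengths_raise(self):
        b = lm.LigamentBundle("x", [(0, 0, 0)], [(10, 0, 0)], lm.SpringLaw(k=100.0))
        with pytest.raises(InvalidParameterError):
            b.tensions()

    def test_per_spring_k_consistency(self):
        b = lm.LigamentBundle(
            "x", [(0, 0, 0)] * 4, [(10, 0, 0)] * 4, lm.SpringLaw(k=1000.0)
        )
        assert b.per_spring_k * b.n_springs == pytest.approx(1000.0, rel=1e-12)


class TestSpringLaw:
    def test_slack_length_property(self):
        law = lm.SpringLaw(k=100.0, eps_r=0.05, L_r=30.0)
        assert law.L_0 == pytest.approx(30.0 / 1.05)
        assert lm.SpringLaw(k=100.0).L_0 is None

    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            lm.SpringLaw(k=0.0)
        with pytest.raises(InvalidParameterError):
            lm.SpringLaw(k=1.0, eps_r=-1.0)
        with pytest.raises(InvalidParameterError):
            lm.SpringLaw(k=1.0, L_r=-5.0)
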