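"""Constitutive-law unit and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from meniscimech import (
    CartilageMaterial,
    DeformationState,
    InvalidDeformationError,
    LigamentMaterial,
    MaterialError,
    MeniscusMaterial,
    cauchy_stress,
    continuity_constant,
    default_meniscus,
    fiber_energy,
    fiber_force_term,
    ligament_spring_force,
    meniscus_compliance,
    prestretch_gradient,
    strain_energy,
    uniaxial_cauchy_stress,
)
from conftest import admissible_gradient


class TestFiberLaw:
    def test_continuity_constant_acl_value(self, ligaments):
        # frozen from a 40-digit evaluation of C3(exp(C4(l*-1))-1) - C5 l*
        assert continuity_constant(ligaments["ACL"]) == pytest.approx(
            -556.748575179304, rel=1e-12
        )

    def test_zero_toe_scale_gives_minus_c5_lambda_star(self):
        mat = LigamentMaterial("toy", 1.0, 0.01, 0.0, 50.0, 100.0, 1.05)
        assert continuity_constant(mat) == pytest.approx(-105.0)

    @pytest.mark.parametrize("name", ["ACL", "PCL", "MCL", "LCL"])
    def test_branch_continuity_at_lambda_star(self, ligaments, name):
        mat = ligaments[name]
        ls = mat.lambda_star
        toe = mat.C3 * (math.exp(mat.C4 * (ls - 1.0)) - 1.0)
        lin = mat.C5 * ls + mat.C6
        assert abs(toe - lin) / abs(lin) < 1e-9

    def test_slack_fibers_carry_nothing(self, ligaments):
        for mat in ligaments.values():
            assert fiber_force_term(0.9, mat) == 0.0
            assert fiber_force_term(1.0, mat) == 0.0

    def test_toe_branch_value(self, ligaments):
        # 0.0139 (exp(116.22 * 0.02) - 1), frozen at high precision
        assert fiber_force_term(1.02, ligaments["ACL"]) == pytest.approx(
            0.128165588262616, rel=1e-12
        )

    @settings(derandomize=True, max_examples=60)
    @given(
        lam=st.floats(1.0, 1.2),
        dlam=st.floats(1e-6, 0.05),
        name=st.sampled_from(["ACL", "PCL", "MCL", "LCL"]),
    )
    def test_nonneg_and_nondecreasing_past_slack(self, lam, dlam, name):
        from meniscimech import default_ligaments

        mat = default_ligaments()[name]
        lo, hi = fiber_force_term(lam, mat), fiber_force_term(lam + dlam, mat)
        assert lo >= 0.0
        assert hi >= lo

    def test_overflow_guard(self):
        mat = LigamentMaterial("hot", 1.0, 0.01, 0.1, 600.0, 100.0, 2.4)
        with pytest.raises(MaterialError):
            fiber_force_term(2.3, mat)  # exp argument 780 > cap

    @pytest.mark.parametrize("name", ["ACL", "LCL"])
    def test_fiber_energy_matches_numeric_integral(self, ligaments, name):
        # independent oracle: quadrature of dF2/dl = (l dF2/dl) / l
        mat = ligaments[name]
        for lam in (1.02, mat.lambda_star, 1.09):
            ref, _ = quad(
                lambda s: fiber_force_term(s, mat) / s, 1.0, lam, limit=200
            )
            assert fiber_energy(lam, mat) == pytest.approx(ref, rel=1e-8)

    def test_fiber_energy_zero_below_slack(self, ligaments):
        assert fiber_energy(0.95, ligaments["ACL"]) == 0.0


class TestEnergyAndStress:
    def test_zero_at_identity(self, ligaments):
        state = DeformationState(np.eye(3))
        for mat in ligaments.values():
            assert strain_energy(state, mat) == pytest.approx(0.0, abs=1e-14)
            assert np.abs(cauchy_stress(state, mat)).max() < 1e-10

    def test_pure_dilation_splits_into_volumetric_and_fiber(self, ligaments):
        # isochoric invariant of a dilation is exactly 3: no matrix term
        mat = ligaments["ACL"]
        s = 1.00333
        state = DeformationState(s * np.eye(3))
        vol = (state.J - 1.0) ** 2 / mat.D1
        fib = fiber_energy(s, mat)
        assert state.I1_bar == pytest.approx(3.0, rel=1e-14)
        assert strain_energy(state, mat) == pytest.approx(vol + fib, rel=1e-12)
        assert fib > 0.0  # dilation stretches the fiber beyond 1

    def test_prestretch_state_has_zero_volumetric_term(self, ligaments):
        state = DeformationState(prestretch_gradient(1.05))
        assert state.J == pytest.approx(1.0, abs=1e-14)

    def test_invalid_deformation_rejected(self):
        with pytest.raises(InvalidDeformationError):
            DeformationState(-np.eye(3))

    def test_stress_matches_finite_difference_gradient(self, ligaments, rng):
        """sigma = J^-1 (dPhi/dF) F^T vs central differences of the energy."""
        h = 1e-6
        worst = 0.0
        mats = list(ligaments.values())
        for k in range(100):
            mat = mats[k % 4]
            F, a = admissible_gradient(rng, mat)
            state = DeformationState(F, a)
            sig = cauchy_stress(state, mat)
            dPhi = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    dPhi[i, j] = (
                        strain_energy(DeformationState(Fp, a), mat)
                        - strain_energy(DeformationState(Fm, a), mat)
                    ) / (2 * h)
            sig_fd = (dPhi @ F.T) / np.linalg.det(F)
            sig_fd = 0.5 * (sig_fd + sig_fd.T)
            err = np.abs(sig - sig_fd).max() / max(np.abs(sig).max(), 1e-12)
            worst = max(worst, err)
        assert worst <= 1e-5

    def test_stress_symmetric(self, ligaments, rng):
        mat = ligaments["PCL"]
        F, a = admissible_gradient(rng, mat)
        sig = cauchy_stress(DeformationState(F, a), mat)
        assert np.abs(sig - sig.T).max() < 1e-10

    def test_fiber_recruitment_monotone_in_uniaxial_stretch(self, ligaments):
        mat = ligaments["ACL"]
        s1 = cauchy_stress(
            DeformationState(prestretch_gradient(1.05)), mat
        )[0, 0]
        s2 = cauchy_stress(
            DeformationState(prestretch_gradient(1.10)), mat
        )[0, 0]
        assert s2 > s1

    def test_small_volumetric_compliance_drives_j_to_one(self, ligaments):
        """Minimising Phi over J at a fixed isochoric part leaves |J-1|
        proportional to D1 (near-incompressibility)."""
        mat = ligaments["ACL"]
        F_bar = prestretch_gradient(1.05)  # det = 1

        def phi_of_J(J, D1):
            m = LigamentMaterial(
                "t", mat.C1, D1, mat.C3, mat.C4, mat.C5, mat.lambda_star
            )
            return strain_energy(DeformationState(J ** (1 / 3) * F_bar), m)

        offsets = {}
        for D1 in (0.01366, 1e-4):
            res = minimize_scalar(
                phi_of_J, bounds=(0.9, 1.1), args=(D1,), method="bounded",
                options={"xatol": 1e-12},
            )
            offsets[D1] = abs(res.x - 1.0)
            assert offsets[D1] <= D1  # |J - 1| bounded by D1 x O(1) stress
        # and the offset shrinks essentially linearly with the compliance
        # (mild deviation allowed: the fiber stress itself moves with J)
        ratio = offsets[1e-4] / 1e-4 / (offsets[0.01366] / 0.01366)
        assert 0.6 < ratio < 1.6


class TestPrestretchGradient:
    def test_five_percent_prestretch_and_unit_determinant(self):
        F = prestretch_gradient(1.05)
        assert F[0, 0] == 1.05
        assert F[1, 1] == pytest.approx(0.97590, abs=5e-6)
        assert np.linalg.det(F) == pytest.approx(1.0, abs=1e-14)

    def test_identity_and_derived_value(self):
        assert np.array_equal(prestretch_gradient(1.0), np.eye(3))
        F = prestretch_gradient(1.1)
        assert F[1, 1] == pytest.approx(0.953462589245592, rel=1e-12)


class TestLigamentSpring:
    def test_unit_total_stretch_gives_zero_force(self, ligaments):
        f = ligament_spring_force(
            1.0 / 1.05, ligaments["MCL"], area=20.0, prestretch=1.05
        )
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_equals_area_times_uniaxial_stress(self, ligaments):
        mat = ligaments["MCL"]
        f = ligament_spring_force(1.0, mat, area=20.0, prestretch=1.05)
        assert f == pytest.approx(20.0 * uniaxial_cauchy_stress(1.05, mat))

    def test_linear_in_area_and_increasing_in_stretch(self, ligaments):
        mat = ligaments["LCL"]
        f1 = ligament_spring_force(1.02, mat, area=10.0)
        f2 = ligament_spring_force(1.02, mat, area=20.0)
        assert f2 == pytest.approx(2.0 * f1)
        lams = np.linspace(0.97, 1.12, 40)
        forces = [ligament_spring_force(l, mat, area=10.0) for l in lams]
        assert np.all(np.diff(forces) > 0)


class TestMeniscusCompliance:
    def test_rz_shear_entry_is_reciprocal_of_grz(self):
        S = meniscus_compliance(default_meniscus())
        assert S[4, 4] == pytest.approx(1.0 / 8.33, rel=1e-12)

    def test_positive_definite_with_defaults(self):
        eig = np.linalg.eigvalsh(meniscus_compliance(default_meniscus()))
        assert eig.min() > 0

    def test_in_plane_isotropy_consistency_within_one_percent(self):
        m = default_meniscus()
        implied = m.E_r / (2.0 * (1.0 + m.nu_rz))
        assert abs(m.G_rz - implied) / implied < 0.01

    def test_isotropic_degenerate_matches_closed_form(self):
        E, nu = 20.0, 0.3
        G = E / (2 * (1 + nu))
        m = MeniscusMaterial(
            E_theta=E, E_z=E, E_r=E, nu_rz=nu, nu_rtheta=nu, nu_ztheta=nu,
            G_rz=G, G_rtheta=G, G_ztheta=G,
        )
        S = meniscus_compliance(m)
        expected = np.zeros((6, 6))
        expected[:3, :3] = (np.eye(3) * (1 + nu) - nu) / E
        expected[3:, 3:] = np.eye(3) / G
        assert np.allclose(S, expected, rtol=1e-12)

    def test_as_printed_convention_rejected_as_not_positive_definite(self):
        m = MeniscusMaterial(theta_ratio_convention="as_printed")
        with pytest.raises(MaterialError):
            meniscus_compliance(m)


class TestParameterValidation:
    def test_cartilage_poisson_range(self):
        with pytest.raises(MaterialError):
            CartilageMaterial(E=10.0, nu=0.55)

    def test_ligament_invariants(self):
        with pytest.raises(MaterialError):
            LigamentMaterial("bad", -1.0, 0.01, 0.1, 10.0, 10.0, 1.05)
        with pytest.raises(MaterialError):
            LigamentMaterial("bad", 1.0, 0.01, 0.1, 10.0, 10.0, 0.99)
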