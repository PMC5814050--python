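"""Contact equilibrium solver tests: laws, balance, symmetry, oracle."""

import numpy as np
import pytest
from dataclasses import replace

from meniscimech import (
    ConvergenceError,
    GeometryError,
    KinematicState,
    LoadCase,
    SolverConfig,
    SolverError,
    assemble_residual,
    brute_force_oracle,
    default_attachments,
    default_meniscus,
    foundation_modulus,
    make_intact_joint,
    meniscus_restraint_force,
    meniscus_restraint_stiffness,
    mirror_joint,
    mirror_materials,
    solve_equilibrium,
    station_contact_pressure,
    total_potential,
)
from meniscimech.solver import minimise_derivative_free


class TestStationPressure:
    def test_open_gap_carries_nothing(self):
        assert station_contact_pressure(0.5, 10.0) == 0.0
        assert station_contact_pressure(0.0, 10.0) == 0.0

    def test_linear_foundation(self):
        assert station_contact_pressure(-0.1, 10.0) == pytest.approx(1.0)

    def test_continuous_at_zero_gap(self):
        eps = 1e-9
        assert station_contact_pressure(-eps, 10.0) < 1e-6

    def test_winkler_constant_from_cartilage(self):
        # confined modulus of E = 10 MPa, nu = 0.45 over a 2 mm layer
        k = foundation_modulus(10.0, 0.45, 2.0)
        assert k == pytest.approx(10.0 * 0.55 / (1.45 * 0.1) / 2.0, rel=1e-12)

    def test_invalid_modulus(self):
        with pytest.raises(SolverError):
            station_contact_pressure(-0.1, -1.0)


class TestMeniscusRestraint:
    def test_zero_shift_zero_force(self, intact_joint, materials):
        men = intact_joint.medial.meniscus
        assert meniscus_restraint_force(
            0.0, men, materials.meniscus, materials.attachments
        ) == 0.0

    def test_hoop_contribution_linear_in_circumferential_modulus(
        self, intact_joint, materials
    ):
        men = intact_joint.lateral.meniscus
        att = materials.attachments
        k1 = meniscus_restraint_stiffness(men, default_meniscus(), att)
        k2 = meniscus_restraint_stiffness(
            men, default_meniscus(E_theta=240.0), att
        )
        horn = att.horn_stiffness("lateral") * 0.5
        assert k2 - k1 == pytest.approx(k1 - horn, rel=1e-12)

    def test_horn_stiffness_side_ratio(self):
        # (161 + 96.3) / (179 + 85.3) with equal horn area and length
        att = default_attachments()
        ratio = att.horn_stiffness("lateral") / att.horn_stiffness("medial")
        assert ratio == pytest.approx(0.973514945138, rel=1e-10)

    def test_restoring_force_linear(self, intact_joint, materials):
        men = intact_joint.medial.meniscus
        f1 = meniscus_restraint_force(
            0.2, men, materials.meniscus, materials.attachments
        )
        f2 = meniscus_restraint_force(
            0.4, men, materials.meniscus, materials.attachments
        )
        assert f2 == pytest.approx(2 * f1)
        assert f1 > 0


@pytest.fixture(scope="module")
def intact_solution(intact_joint, materials, full_load):
    return solve_equilibrium(intact_joint, materials, full_load)


@pytest.fixture(scope="module")
def cml_solution(intact_joint, materials):
    return solve_equilibrium(
        intact_joint,
        materials,
        LoadCase(1000.0, 10, constrain_mediolateral=True),
    )


class TestResidual:
    def test_zero_at_contact_free_unstretched_reference(self, materials):
        """No load, no prestretch, surfaces standing clear: exact balance."""
        geom = make_intact_joint({"wedge_clearance": 1.0})
        r = assemble_residual(
            KinematicState.from_vector(np.zeros(5)),
            geom,
            materials,
            LoadCase(0.0, 1),
            SolverConfig(prestretch=1.0),
        )
        assert np.abs(r).max() == 0.0

    def test_matches_finite_difference_of_potential(
        self, intact_joint, materials, full_load
    ):
        state = KinematicState.from_vector([0.1, -0.3, 0.002, 0.05, 0.08])
        r = assemble_residual(state, intact_joint, materials, full_load)
        q = state.as_vector()
        h = 1e-6
        for j in range(5):
            qp, qm = q.copy(), q.copy()
            qp[j] += h
            qm[j] -= h
            fd = (
                total_potential(
                    KinematicState.from_vector(qp), intact_joint, materials,
                    full_load,
                )
                - total_potential(
                    KinematicState.from_vector(qm), intact_joint, materials,
                    full_load,
                )
            ) / (2 * h)
            assert r[j] == pytest.approx(fd, rel=2e-5, abs=1e-4)

    def test_converged_solution_satisfies_tolerance(self, intact_solution):
        assert intact_solution.converged
        assert intact_solution.residual_norm <= 1e-6 * 1000.0


class TestEquilibrium:
    def test_symmetric_joint_centred(self, symmetric_setup, full_load):
        geom, mats = symmetric_setup
        sol = solve_equilibrium(geom, mats, full_load)
        assert abs(sol.kinematics_absolute.u) < 1e-8
        assert sol.constraint_force == 0.0
        cml = solve_equilibrium(
            geom, mats, LoadCase(1000.0, 10, constrain_mediolateral=True)
        )
        assert abs(cml.constraint_force) < 1e-6

    def test_steeper_lateral_slope_translates_femur_medially(
        self, intact_solution
    ):
        # intact: beta_L > beta_M, so u > 0 (medial femur translation)
        assert intact_solution.kinematics_absolute.u > 0

    def test_cml_holds_translation_with_positive_reaction(self, cml_solution):
        assert abs(cml_solution.kinematics_absolute.u) < 1e-12
        assert cml_solution.constraint_force > 0

    def test_axial_balance_against_applied_load_without_ligaments(
        self, materials
    ):
        geom = replace(make_intact_joint(), ligaments=())
        sol = solve_equilibrium(geom, materials, LoadCase(1000.0, 10))
        assert sol.contact.axial_resultant() == pytest.approx(
            1000.0, rel=1e-6
        )

    def test_no_tensile_station_pressures(self, intact_solution):
        for patch in intact_solution.contact.patches.values():
            assert patch.pressure.min() >= 0.0

    def test_mirror_antisymmetry(self, intact_joint, materials, full_load):
        g2 = mirror_joint(intact_joint)
        m2 = mirror_materials(materials)
        s1 = solve_equilibrium(intact_joint, materials, full_load)
        s2 = solve_equilibrium(g2, m2, full_load)
        assert s1.kinematics_absolute.u + s2.kinematics_absolute.u == (
            pytest.approx(0.0, abs=1e-9)
        )
        c1 = solve_equilibrium(
            intact_joint, materials,
            LoadCase(1000.0, 10, constrain_mediolateral=True),
        )
        c2 = solve_equilibrium(
            g2, m2, LoadCase(1000.0, 10, constrain_mediolateral=True)
        )
        assert c1.constraint_force + c2.constraint_force == pytest.approx(
            0.0, abs=1e-8
        )
        assert c1.kinematics_absolute.w_shift["medial"] == pytest.approx(
            c2.kinematics_absolute.w_shift["lateral"], abs=1e-10
        )

    def test_constraint_consistency(self, intact_joint, materials, cml_solution):
        """Free solve under minus the recorded F_M-L reproduces u = 0."""
        sol = solve_equilibrium(
            intact_joint,
            materials,
            LoadCase(1000.0, 10, mediolateral_force=-cml_solution.constraint_force),
        )
        assert abs(sol.kinematics_absolute.u) < 1e-6

    def test_extrusion_resultants_nondecreasing_along_ramp(
        self, intact_solution
    ):
        em = [i["extrusion_medial"] for i in intact_solution.increments]
        el = [i["extrusion_lateral"] for i in intact_solution.increments]
        assert np.all(np.diff(em) > -1e-9)
        assert np.all(np.diff(el) > -1e-9)

    def test_extrusion_force_balances_restraint(
        self, intact_solution, intact_joint, materials
    ):
        """At equilibrium the wedge outward force equals k_w * w exactly."""
        for side in ("medial", "lateral"):
            w = intact_solution.kinematics_absolute.w_shift[side]
            k = meniscus_restraint_stiffness(
                intact_joint.compartment(side).meniscus,
                materials.meniscus,
                materials.attachments,
            )
            assert intact_solution.contact.extrusion_force(side) == (
                pytest.approx(k * w, rel=1e-6)
            )

    def test_nonconvergence_raises_with_diagnostic(
        self, intact_joint, materials
    ):
        with pytest.raises(ConvergenceError) as err:
            solve_equilibrium(
                intact_joint,
                materials,
                LoadCase(1000.0, 1),
                SolverConfig(max_iterations=1),
            )
        assert err.value.residual_norm > 0


class TestOracle:
    def test_quadratic_two_dof_matches_closed_form(self):
        A = np.array([[4.0, 1.2], [1.2, 3.0]])
        b = np.array([1.0, -2.0])

        def fun(x):
            return 0.5 * x @ A @ x - b @ x

        x, _ = minimise_derivative_free(
            fun, np.zeros(2), spans=np.array([3.0, 3.0]), resolution=1e-8
        )
        assert np.allclose(x, np.linalg.solve(A, b), atol=1e-6)

    def test_symmetric_joint_oracle_centred(self, symmetric_setup):
        geom, mats = symmetric_setup
        res = brute_force_oracle(
            geom, mats, LoadCase(600.0, 5), grid_spec={"resolution": 1e-4}
        )
        assert abs(res.state.u) <= 2 * res.resolution

    def test_newton_matches_energy_minimum_on_randomized_joints(
        self, materials, rng
    ):
        """Independent derivative-free minimisation agrees with Newton on
        ten randomized small instances within twice the grid resolution."""
        for _ in range(10):
            cfg = {
                "h_medial": float(rng.uniform(3.6, 5.0)),
                "h_lateral": float(rng.uniform(3.8, 5.2)),
                "beta_target_medial": float(rng.uniform(24.0, 30.0)),
                "beta_target_lateral": float(rng.uniform(28.0, 34.0)),
                "plateau_curvature_medial": float(rng.uniform(-0.049, -0.03)),
                "plateau_curvature_lateral": float(rng.uniform(0.0, 0.04)),
            }
            geom = make_intact_joint(cfg)
            load = LoadCase(float(rng.uniform(400.0, 1200.0)), 5)
            newton = solve_equilibrium(geom, materials, load)
            oracle = brute_force_oracle(
                geom, materials, load, grid_spec={"resolution": 1e-4}
            )
            dev = np.abs(
                oracle.state.as_vector()
                - newton.kinematics_absolute.as_vector()
            )
            assert dev.max() <= 2 * oracle.resolution
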