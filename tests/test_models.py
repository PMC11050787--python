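"""Equilibrium solvers: reference model, emulator, reference configuration."""

import numpy as np
import pytest

import vivolig as vl
from vivolig.compliance import RIGID
from vivolig.contact import ContactEngine, ContactLaw
from vivolig.emulator import (
    FlexionProtocol,
    sensed_pose_from_true,
    set_reference_configuration,
    solve_step_equilibrium,
    worked_example_force_vs_load,
)
from vivolig.kinematics import JointPose, pose_to_transform
from vivolig.ligaments import LigamentApparatus, LigamentBundle
from vivolig.reference_model import ReferenceRunSpec, run_reference_flexion, solve_reference_equilibrium


class TestReferenceEquilibrium:
    def test_reference_state_converges_and_balances(self, reference_state, calibrated_apparatus, engine):
        pose, app = reference_state
        res, extras = solve_reference_equilibrium(0.0, app, engine, pose)
        assert res.converged
        assert res.residual_force_N <= 0.5
        assert res.residual_moment_Nmm <= 50.0
        assert extras["axial_force_N"] > 100.0
        assert extras["contact_count"] > 0

    def test_symmetric_fixture_stays_in_sagittal_plane(self, surfaces, engine):
        # mirror-symmetric two-bundle apparatus: ML translation and
        # adduction must remain zero at extension
        kw = dict(stiffness_k=2500.0, reference_strain=0.05)
        app = LigamentApparatus(
            [
                LigamentBundle("V_m", [0.0, 22.0, 0.0], [0.0, 22.0, -50.0], **kw),
                LigamentBundle("V_l", [0.0, -22.0, 0.0], [0.0, -22.0, -50.0], **kw),
            ]
        )
        nominal = vl.nominal_reference_pose()
        app.calibrate(pose_to_transform(nominal))
        res, _ = solve_reference_equilibrium(0.0, app, engine, nominal)
        assert res.converged
        assert abs(res.pose.ml) < 1e-3
        assert abs(res.pose.adduction) < 1e-3

    def test_loss_of_contact_flagged(self, engine):
        app = LigamentApparatus([])
        pose = JointPose(dp=-30.0)  # surfaces separated, nothing to balance
        res, extras = solve_reference_equilibrium(0.0, app, engine, pose)
        assert not res.in_contact
        assert "loss of contact" in res.message
        assert extras["axial_force_N"] == 0.0

    def test_stiffer_foundation_smaller_penetration(self, surfaces, apparatus):
        femoral, tibial = surfaces
        nominal = vl.nominal_reference_pose()
        depths = {}
        for k in (30.0, 60.0):
            eng = ContactEngine(tibial, femoral, ContactLaw(foundation_modulus=k))
            app = apparatus.copy().calibrate(pose_to_transform(nominal))
            res, extras = solve_reference_equilibrium(0.0, app, eng, nominal)
            assert res.converged
            depths[k] = extras["max_depth_mm"]
        assert depths[60.0] < depths[30.0]


class TestReferenceConfiguration:
    @pytest.mark.parametrize(
        "preload, expected",
        [
            (800.0, 0.7 + 0.0006 * 300.0),  # linear branch
            (0.0, 0.0),
            (100.0, 0.7 * (100.0 / 500.0) ** (3.0 / 7.0)),  # power toe
        ],
    )
    def test_reference_deflection(self, reference_state, apparatus, compliance_curve, preload, expected):
        pose, _ = reference_state
        cfg = set_reference_configuration(pose, preload, compliance_curve, apparatus)
        assert cfg.reference_deflection == pytest.approx(expected, abs=1e-12)

    def test_rest_lengths_calibrated_at_reference(self, reference_state, apparatus, compliance_curve):
        pose, _ = reference_state
        cfg = set_reference_configuration(pose, 800.0, compliance_curve, apparatus)
        t = pose_to_transform(pose)
        for b in cfg.apparatus:
            assert b.strain(t) == pytest.approx(b.reference_strain, abs=1e-9)

    def test_negative_preload_rejected(self, reference_state, apparatus, compliance_curve):
        with pytest.raises(ValueError):
            set_reference_configuration(reference_state[0], -5.0, compliance_curve, apparatus)


class TestSensedPose:
    def test_at_preload_sensed_equals_true(self, compliance_curve):
        true = JointPose(flexion=30.0, dp=-24.8)
        delta_ref = float(compliance_curve.displacement_at_load(800.0))
        sensed = sensed_pose_from_true(true, 800.0, compliance_curve, delta_ref)
        np.testing.assert_allclose(sensed.as_array(), true.as_array(), atol=1e-12)

    def test_peak_load_shift(self, compliance_curve):
        true = JointPose(dp=-24.8)
        sensed = sensed_pose_from_true(true, 3000.0, compliance_curve, 0.0)
        assert sensed.dp - true.dp == pytest.approx(2.2)  # ligaments shortened
        assert sensed.ap == true.ap and sensed.flexion == true.flexion

    def test_rigid_actuator_no_shift(self):
        true = JointPose(dp=-24.8)
        sensed = sensed_pose_from_true(true, 3000.0, RIGID, 0.0)
        np.testing.assert_allclose(sensed.as_array(), true.as_array())


class TestWorkedExample:
    def test_monotone_decreasing_and_endpoints(self, exemplary_bundle, compliance_curve):
        loads = np.linspace(30.0, 3000.0, 50)
        df = worked_example_force_vs_load(exemplary_bundle, compliance_curve, loads)
        assert np.all(np.diff(df.sensed_force_N.values) < 0)
        assert df.sensed_force_N.iloc[-1] == pytest.approx(108.0, rel=0.02)
        assert df.s1_mm.iloc[-1] == pytest.approx(2.2)

    def test_rigid_actuator_constant_force(self, exemplary_bundle):
        df = worked_example_force_vs_load(exemplary_bundle, RIGID, np.linspace(0.0, 3000.0, 10))
        np.testing.assert_allclose(df.sensed_force_N.values, 264.0, atol=1e-9)
        np.testing.assert_allclose(df.s1_mm.values, 0.0)


class TestProtocol:
    def test_non_monotone_schedule_rejected(self):
        with pytest.raises(ValueError):
            FlexionProtocol(schedule=(0.0, 2.0, 1.0))

    def test_step_above_two_degrees_rejected(self):
        with pytest.raises(ValueError):
            FlexionProtocol(schedule=(0.0, 3.0))

    def test_default_schedule_is_one_degree_grid(self):
        p = FlexionProtocol()
        assert len(p.schedule) == 81
        assert p.schedule[0] == 0.0 and p.schedule[-1] == 80.0


class TestEmulatorStep:
    def test_zero_flexion_step_matches_reference(self, reference_state, apparatus, engine, compliance_curve):
        pose, app = reference_state
        # deflection fixed point at the first step; with the preload near
        # the actual 0-degree contact force the correction is small
        cfg = set_reference_configuration(pose, 800.0, compliance_curve, apparatus)
        res, extras = solve_step_equilibrium(0.0, pose, cfg, engine)
        assert res.converged
        assert extras["deflection_mm"] == pytest.approx(
            float(compliance_curve.displacement_at_load(extras["axial_force_N"])), abs=1e-3
        )

    def test_rigid_step_identical_to_reference_model(self, reference_state, apparatus, engine):
        pose, app = reference_state
        cfg = set_reference_configuration(pose, 800.0, RIGID, apparatus)
        res_e, ex_e = solve_step_equilibrium(10.0, pose, cfg, engine)
        res_r, ex_r = solve_reference_equilibrium(10.0, app, engine, pose)
        np.testing.assert_allclose(res_e.pose.as_array(), res_r.pose.as_array(), atol=1e-9)
        assert ex_e["axial_force_N"] == pytest.approx(ex_r["axial_force_N"], abs=1e-6)


class TestDeterminism:
    def test_identical_pcl_scales_identical_results(self, surfaces, apparatus, reference_state):
        femoral, tibial = surfaces
        pose, _ = reference_state
        spec = ReferenceRunSpec(
            schedule=[0.0, 2.0], apparatus=apparatus, tibial_surface=tibial, femoral_surface=femoral
        )
        a = run_reference_flexion(spec, reference_pose=pose)
        b = run_reference_flexion(spec, reference_pose=pose)
        assert a.table.equals(b.table)
        assert a.bundle_forces_true.equals(b.bundle_forces_true)
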