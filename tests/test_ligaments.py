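"""Ligament force law, calibration and apparatus mechanics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vivolig as vl
from vivolig.kinematics import JointPose, RigidTransform, pose_to_transform
from vivolig.ligaments import (
    DegenerateBundleError,
    LigamentApparatus,
    LigamentBundle,
    UncalibratedBundleError,
    force_from_strain,
    rest_length_from_reference,
)

IDENTITY = RigidTransform(np.eye(3), np.zeros(3))


class TestForceLaw:
    @pytest.mark.parametrize(
        "strain, k, eps_l, expected",
        [
            (0.0, 3300.0, 0.03, 0.0),  # slack ligament
            (-0.5, 3300.0, 0.03, 0.0),  # compression: cables carry no load
            (0.06, 3300.0, 0.03, 99.0),  # branch junction, k*eps_l
            (0.11, 3300.0, 0.03, 264.0),  # linear branch at reference strain
            (0.03, 3300.0, 0.03, 3300.0 * 0.03**2 / 0.12),  # toe region
        ],
    )
    def test_values(self, strain, k, eps_l, expected):
        assert force_from_strain(strain, k, eps_l) == pytest.approx(expected, abs=1e-9)

    def test_shortened_fixture_force_near_bench_value(self):
        # strain of the bench bundle after 2.2 mm shortening of 51.615 mm
        strain = (51.615 - 2.2) / 46.5 - 1.0
        f = force_from_strain(strain, 3300.0, 0.03)
        assert f == pytest.approx(108.0, rel=0.02)

    def test_continuity_and_slope_at_transition(self):
        k, eps_l = 3300.0, 0.03
        h = 1e-8
        assert abs(force_from_strain(2 * eps_l - h, k, eps_l) - force_from_strain(2 * eps_l + h, k, eps_l)) < 1e-3
        slope_toe = (force_from_strain(2 * eps_l, k, eps_l) - force_from_strain(2 * eps_l - h, k, eps_l)) / h
        slope_lin = (force_from_strain(2 * eps_l + h, k, eps_l) - force_from_strain(2 * eps_l, k, eps_l)) / h
        assert slope_toe == pytest.approx(k, rel=1e-6)
        assert slope_lin == pytest.approx(k, rel=1e-6)

    @given(
        e1=st.floats(-0.2, 0.5),
        e2=st.floats(-0.2, 0.5),
        k=st.floats(10.0, 1e4),
        eps_l=st.floats(1e-3, 0.2),
    )
    def test_monotone_nondecreasing(self, e1, e2, k, eps_l):
        lo, hi = min(e1, e2), max(e1, e2)
        assert force_from_strain(lo, k, eps_l) <= force_from_strain(hi, k, eps_l) + 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            force_from_strain(0.1, -1.0, 0.03)
        with pytest.raises(ValueError):
            force_from_strain(0.1, 3300.0, 0.0)


class TestRestLength:
    def test_exemplary_fixture_distance(self):
        assert rest_length_from_reference(51.615, reference_strain=0.11) == pytest.approx(46.5)

    def test_zero_reference_strain(self):
        assert rest_length_from_reference([0, 0, 0], [0, 0, -10], 0.0) == pytest.approx(10.0)

    def test_degenerate_points_raise(self):
        with pytest.raises(DegenerateBundleError):
            rest_length_from_reference([1, 2, 3], [1, 2, 3], 0.1)

    @given(
        dist=st.floats(1.0, 200.0),
        eps_r=st.floats(-0.5, 0.5),
    )
    def test_calibration_round_trip(self, dist, eps_r):
        l0 = rest_length_from_reference(dist, reference_strain=eps_r)
        assert dist / l0 - 1.0 == pytest.approx(eps_r, abs=1e-9)


class TestBundle:
    def make_vertical(self, strain=0.11, scale=1.0):
        l0 = 46.5
        return LigamentBundle(
            name="b",
            origin=[0, 0, 0],
            insertion=[0, 0, -l0 * (1 + strain)],
            stiffness_k=3300.0,
            reference_strain=strain,
            rest_length=l0,
            stiffness_scale=scale,
        )

    def test_force_direction_and_magnitude(self):
        b = self.make_vertical()
        f, mag = b.force_vector(IDENTITY)
        assert mag == pytest.approx(264.0)
        # tension pulls the tibial insertion up toward the femoral origin
        np.testing.assert_allclose(f, [0.0, 0.0, 264.0], atol=1e-9)

    def test_slack_bundle_zero_vector(self):
        b = self.make_vertical(strain=-0.05)
        f, mag = b.force_vector(IDENTITY)
        assert mag == 0.0
        np.testing.assert_allclose(f, 0.0)

    def test_resected_bundle_zero_at_any_strain(self):
        b = self.make_vertical(strain=0.3, scale=0.0)
        _, mag = b.force_vector(IDENTITY)
        assert mag == 0.0

    def test_uncalibrated_raises(self):
        b = LigamentBundle("u", [0, 0, 0], [0, 0, -10], 1000.0, 0.05)
        with pytest.raises(UncalibratedBundleError):
            b.strain(IDENTITY)

    def test_calibrate_reproduces_reference_strain(self):
        b = LigamentBundle("c", [1.0, 2.0, 3.0], [-4.0, 0.0, -40.0], 1500.0, 0.07)
        t = pose_to_transform(JointPose(flexion=12.0, dp=-20.0))
        b.calibrate(t)
        assert b.strain(t) == pytest.approx(0.07, abs=1e-9)


class TestApparatus:
    def mirror_pair(self):
        kw = dict(stiffness_k=2000.0, reference_strain=0.05)
        a = LigamentBundle("L", [0, -30, 0], [0, -30, -50], **kw)
        b = LigamentBundle("R", [0, 30, 0], [0, 30, -50], **kw)
        return LigamentApparatus([a, b]).calibrate(IDENTITY)

    def test_empty_apparatus_zero_wrench(self):
        assert np.allclose(LigamentApparatus([]).wrench(IDENTITY), 0.0)

    def test_single_bundle_wrench_matches_bundle(self):
        app = self.mirror_pair()
        single = LigamentApparatus([app.bundles[0]])
        t = pose_to_transform(JointPose(dp=1.5))
        f, _ = app.bundles[0].force_vector(t)
        w = single.wrench(t)
        np.testing.assert_allclose(w[:3], f, atol=1e-12)

    def test_additivity_of_disjoint_apparatuses(self):
        app = self.mirror_pair()
        t = pose_to_transform(JointPose(flexion=5.0, dp=2.0))
        w_union = app.wrench(t, moment_reference_point=[1.0, 2.0, 3.0])
        w_sum = sum(
            LigamentApparatus([b]).wrench(t, moment_reference_point=[1.0, 2.0, 3.0]) for b in app.bundles
        )
        np.testing.assert_allclose(w_union, w_sum, atol=1e-9)

    def test_mirror_symmetric_pair_no_ml_force(self):
        app = self.mirror_pair()
        w = app.wrench(pose_to_transform(JointPose(dp=2.0)))
        assert abs(w[1]) < 1e-9  # medial-lateral component cancels

    def test_duplicate_names_rejected(self):
        b = LigamentBundle("x", [0, 0, 0], [0, 0, -10], 100.0, 0.0)
        b2 = LigamentBundle("x", [1, 0, 0], [0, 0, -10], 100.0, 0.0)
        with pytest.raises(ValueError):
            LigamentApparatus([b, b2])

    def test_resection_scales_matching_prefix_only(self, apparatus):
        app = apparatus.copy()
        app.set_resection("PCL", 0.5)
        scaled = [b.name for b in app if b.stiffness_scale == 0.5]
        assert sorted(scaled) == ["PCL_am", "PCL_pl"]
        assert all(b.stiffness_scale == 1.0 for b in app if not b.name.startswith("PCL"))

    def test_resection_unknown_prefix_raises(self, apparatus):
        with pytest.raises(KeyError):
            apparatus.copy().set_resection("XYZ", 0.5)

    @given(scale=st.floats(0.0, 1.0))
    def test_resection_linear_in_scale(self, scale):
        kw = dict(stiffness_k=2000.0, reference_strain=0.08)
        b1 = LigamentBundle("PCL_x", [0, 0, 0], [0, 0, -50], **kw)
        app = LigamentApparatus([b1]).calibrate(IDENTITY)
        t = pose_to_transform(JointPose(dp=-2.0))
        full = app.bundles[0].force_magnitude(t)
        app.set_resection("PCL", scale)
        assert app.bundles[0].force_magnitude(t) == pytest.approx(scale * full, abs=1e-9)

    def test_yaml_round_trip(self, apparatus, tmp_path):
        p = tmp_path / "lig.yaml"
        apparatus.to_yaml(p)
        back = LigamentApparatus.from_yaml(p)
        assert [b.name for b in back] == [b.name for b in apparatus]
        np.testing.assert_allclose(back.bundles[0].origin, apparatus.bundles[0].origin)
        assert back.bundles[3].stiffness_k == apparatus.bundles[3].stiffness_k
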