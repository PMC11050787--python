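"""Elastic-foundation contact: penetration fields and wrenches."""

import numpy as np
import pytest
import trimesh

from vivolig.contact import ContactEngine, ContactLaw, ImplantSurface, contact_wrench, penetration_field
from vivolig.kinematics import RigidTransform

IDENTITY = RigidTransform(np.eye(3), np.zeros(3))


def plate(half: float, n: int, z: float, normal_up: bool) -> trimesh.Trimesh:
    """Square plate mesh in the z = const plane with chosen outward normal."""
    xs = np.linspace(-half, half, n + 1)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b, c, d = a + 1, a + n + 1, a + n + 2
            faces += [[a, b, c], [b, d, c]]
    mesh = trimesh.Trimesh(verts, np.array(faces), process=False)
    if (mesh.face_normals[:, 2].mean() > 0) != normal_up:
        mesh = trimesh.Trimesh(verts, np.array(faces)[:, ::-1], process=False)
    return mesh


@pytest.fixture(scope="module")
def flat_pair():
    # femoral material above z=0 (outward normal -z); small tibial plate
    # whose articular side faces up, raised by d -> uniform penetration d
    femoral = ImplantSurface(plate(20.0, 40, 0.0, normal_up=False), "femoral")
    tibial = ImplantSurface(plate(5.0, 10, 0.0, normal_up=True), "tibial")
    return tibial, femoral


def lift(d: float) -> RigidTransform:
    return RigidTransform(np.eye(3), np.array([0.0, 0.0, d]))


class TestPenetrationField:
    def test_separated_surfaces_all_zero(self, flat_pair):
        tibial, femoral = flat_pair
        field = penetration_field(tibial, femoral, lift(-1.0))
        assert field.max_depth == 0.0
        assert field.contact_count == 0

    def test_uniform_penetration_depth(self, flat_pair):
        tibial, femoral = flat_pair
        field = penetration_field(tibial, femoral, lift(0.05))
        assert field.contact_count == len(field.depths)
        np.testing.assert_allclose(field.depths, 0.05, atol=1e-12)

    def test_sphere_on_plane_pole_depth(self):
        # sphere of radius 20 mm pressed 0.1 mm through the plane
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=20.0)
        sphere.apply_translation([0.0, 0.0, 19.9])
        femoral = ImplantSurface(sphere, "femoral")
        tibial = ImplantSurface(plate(10.0, 40, 0.0, normal_up=True), "tibial")
        field = penetration_field(tibial, femoral, IDENTITY)
        assert field.max_depth == pytest.approx(0.1, abs=0.02)

    def test_swapped_roles_same_max_depth(self):
        sphere = trimesh.creation.icosphere(subdivisions=5, radius=20.0)
        sphere.apply_translation([0.0, 0.0, 19.9])
        plane_up = plate(10.0, 40, 0.0, normal_up=True)
        a = penetration_field(ImplantSurface(plane_up, "tibial"), ImplantSurface(sphere, "femoral"), IDENTITY)
        b = penetration_field(ImplantSurface(sphere, "tibial"), ImplantSurface(plane_up, "femoral"), IDENTITY)
        assert a.max_depth == pytest.approx(b.max_depth, abs=0.02)

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValueError):
            ImplantSurface(trimesh.Trimesh(), "femoral")


class TestContactWrench:
    def test_no_penetration_zero_wrench(self, flat_pair):
        tibial, femoral = flat_pair
        w, axial = contact_wrench(tibial, femoral, lift(-0.5))
        np.testing.assert_allclose(w, 0.0)
        assert axial == 0.0

    @pytest.mark.parametrize("n_tib, rel_tol", [(10, 0.01), (40, 0.002)])
    def test_flat_on_flat_closed_form(self, n_tib, rel_tol):
        femoral = ImplantSurface(plate(20.0, 40, 0.0, normal_up=False), "femoral")
        tibial = ImplantSurface(plate(5.0, n_tib, 0.0, normal_up=True), "tibial")
        d, area, k = 0.05, 100.0, 30.0
        w, axial = contact_wrench(tibial, femoral, lift(d), ContactLaw(foundation_modulus=k))
        assert axial == pytest.approx(k * d * area, rel=rel_tol)
        # force pushes the tibia back out, distally
        assert w[2] == pytest.approx(-k * d * area, rel=rel_tol)

    def test_normal_force_monotone_in_penetration(self, flat_pair):
        tibial, femoral = flat_pair
        engine = ContactEngine(tibial, femoral)
        forces = [engine.wrench(lift(d))[1] for d in (0.01, 0.03, 0.06, 0.1)]
        assert all(a < b for a, b in zip(forces, forces[1:]))

    def test_zero_friction_no_tangential(self, flat_pair):
        tibial, femoral = flat_pair
        law = ContactLaw(friction_mu=0.0)
        w, _ = contact_wrench(tibial, femoral, lift(0.05), law, relative_slip=np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(w[:2], 0.0, atol=1e-12)

    def test_friction_opposes_slip_and_saturates(self, flat_pair):
        tibial, femoral = flat_pair
        law = ContactLaw(friction_mu=0.1, regularization_slip=0.01)
        engine = ContactEngine(tibial, femoral, law)
        w, normal, _ = engine.wrench(lift(0.05), relative_slip=np.array([5.0, 0.0, 0.0]))
        assert w[0] < 0  # opposes +x slip of the tibia
        assert abs(w[0]) <= 0.1 * normal * (1 + 1e-9)
        assert abs(w[0]) == pytest.approx(0.1 * normal, rel=1e-3)  # deep in saturation

    def test_moment_transfer_consistency(self, flat_pair):
        # wrench about two reference points obeys M2 = M1 + (r1 - r2) x F
        tibial, femoral = flat_pair
        engine = ContactEngine(tibial, femoral)
        t = lift(0.05)
        r1, r2 = np.array([0.0, 0.0, 0.0]), np.array([3.0, -2.0, 5.0])
        w1, _, _ = engine.wrench(t, moment_reference_point=r1)
        w2, _, _ = engine.wrench(t, moment_reference_point=r2)
        np.testing.assert_allclose(w2[:3], w1[:3], atol=1e-12)
        np.testing.assert_allclose(w2[3:], w1[3:] + np.cross(r1 - r2, w1[:3]), atol=1e-9)

    def test_invalid_law_rejected(self):
        with pytest.raises(ValueError):
            ContactLaw(foundation_modulus=-1.0)
        with pytest.raises(ValueError):
            ContactLaw(friction_mu=-0.1)
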