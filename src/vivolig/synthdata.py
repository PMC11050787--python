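"""Synthetic test fixtures: implant surfaces, ligament sets, compliance anchors.

Nothing in this module is a measured implant.  The geometry is a
deliberately simple stand-in for a bicondylar PCL-retaining fixed-bearing
total knee replacement: two toroidal femoral condyle patches (single
sagittal radius, no decreasing-radius J-curve) articulating with two
paraboloid-dished tibial patches.  Ligament insertion coordinates and
stiffnesses are fixture constants chosen for anatomical plausibility and
for reproducing the qualitative passive-flexion behaviour of a knee
(posterior structures taut in extension, near-isometric collaterals,
posterior cruciate engaging with flexion); they are documented stand-ins,
not published anatomical data.

Frames
------
Femoral frame: origin at the mid-condylar point on the gimbal flexion
axis; x anterior, y medial, z proximal.  Tibial frame: origin at the
centre of the tibial plateau (dish bottoms at z = 0); axes parallel to the
femoral frame at the zero pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .compliance import DEFAULT_ANGLE_SCALE, ComplianceCurve
from .contact import ImplantSurface
from .kinematics import JointPose
from .ligaments import LigamentApparatus, LigamentBundle

__all__ = [
    "FixtureSpec",
    "make_implant_surfaces",
    "make_ligament_set",
    "make_exemplary_lcl_fixture",
    "default_compliance_anchors",
    "nominal_reference_pose",
    "EXEMPLARY_LCL_REST_LENGTH_MM",
]

#: Rest length of the exemplary lateral-collateral fixture bundle (mm).
#: Not a printed value: it is the unique rest length for which shortening
#: the insertion distance by the 2.2 mm peak unsensed deflection drives the
#: force of the k = 3300 N/strain, 11 %-reference-strain bundle from its
#: pretension down to the reported ~108 N (1-D solve of the force law).
EXEMPLARY_LCL_REST_LENGTH_MM = 46.5


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic implant geometry.

    Radii in mm.  ``resolution`` scales both meshes; the default yields a
    few thousand faces per component, enough for ~1 mm contact sampling.
    """

    condyle_sagittal_radius: float = 25.0
    condyle_frontal_radius: float = 20.0
    condylar_spacing: float = 44.0  # centre-to-centre, mm
    dish_sagittal_radius: float = 40.0
    dish_frontal_radius: float = 24.0
    dish_half_length: float = 18.0  # tibial patch half-extent, anterior-posterior, mm
    dish_half_width: float = 14.0  # tibial patch half-extent, medial-lateral, mm
    resolution: float = 1.0
    ligament_seed: int = 0
    ligament_jitter_mm: float = 0.0

    def __post_init__(self) -> None:
        if min(
            self.condyle_sagittal_radius,
            self.condyle_frontal_radius,
            self.dish_sagittal_radius,
            self.dish_frontal_radius,
        ) <= 0:
            raise ValueError("all radii must be positive")
        if self.condyle_frontal_radius > self.dish_frontal_radius:
            raise ValueError("conforming contact requires femoral frontal radius <= tibial dish radius")
        if self.condyle_sagittal_radius > self.dish_sagittal_radius:
            raise ValueError("conforming contact requires femoral sagittal radius <= tibial dish radius")


def _grid_mesh(vertices: np.ndarray, nu: int, nv: int, flip: bool = False) -> trimesh.Trimesh:
    """Triangulate a structured (nu+1) x (nv+1) vertex grid."""
    faces = []
    for i in range(nu):
        for j in range(nv):
            a = i * (nv + 1) + j
            b = a + 1
            c = a + (nv + 1)
            d = c + 1
            if flip:
                faces.append([a, c, b])
                faces.append([b, c, d])
            else:
                faces.append([a, b, c])
                faces.append([b, d, c])
    return trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)


def _condyle_patch(spec: FixtureSpec, side: float) -> trimesh.Trimesh:
    """One toroidal condyle patch; ``side`` is +1 medial, -1 lateral.

    The torus centre circle (radius ``c``) lies in the sagittal plane of
    the condyle and is swept about the gimbal (y) axis; the tube radius is
    the frontal radius.  theta = 0 points straight distal, positive
    anterior; contact during flexion ``f`` happens near theta = -f.
    """
    r_tube = spec.condyle_frontal_radius
    c = spec.condyle_sagittal_radius - r_tube
    y_c = side * spec.condylar_spacing / 2.0
    n_theta = max(8, int(round(96 * spec.resolution)))
    n_phi = max(6, int(round(36 * spec.resolution)))
    theta = np.deg2rad(np.linspace(-115.0, 35.0, n_theta + 1))
    phi = np.deg2rad(np.linspace(-55.0, 55.0, n_phi + 1))
    th, ph = np.meshgrid(theta, phi, indexing="ij")
    # radial direction in the sagittal plane (away from the gimbal axis)
    ux, uz = np.sin(th), -np.cos(th)
    x = c * np.sin(th) + r_tube * np.cos(ph) * ux
    y = y_c + r_tube * np.sin(ph)
    z = -c * np.cos(th) + r_tube * np.cos(ph) * uz
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    mesh = _grid_mesh(verts, n_theta, n_phi, flip=False)
    # enforce outward normals (away from the tube centre line)
    centers = mesh.triangles_center
    ang = np.arctan2(centers[:, 0], -centers[:, 2])
    circ = np.column_stack([c * np.sin(ang), np.full(len(centers), y_c), -c * np.cos(ang)])
    outward = centers - circ
    if np.mean(np.einsum("ij,ij->i", mesh.face_normals, outward)) < 0:
        mesh = trimesh.Trimesh(mesh.vertices, mesh.faces[:, ::-1], process=False)
    return mesh


def _dish_patch(spec: FixtureSpec, side: float) -> trimesh.Trimesh:
    """One paraboloid tibial dish patch (tibial frame, bottom at z = 0)."""
    y_c = side * spec.condylar_spacing / 2.0
    n_x = max(8, int(round(30 * spec.resolution)))
    n_y = max(6, int(round(24 * spec.resolution)))
    xs = np.linspace(-spec.dish_half_length, spec.dish_half_length, n_x + 1)
    ys = y_c + np.linspace(-spec.dish_half_width, spec.dish_half_width, n_y + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gz = gx**2 / (2.0 * spec.dish_sagittal_radius) + (gy - y_c) ** 2 / (2.0 * spec.dish_frontal_radius)
    verts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    mesh = _grid_mesh(verts, n_x, n_y, flip=False)
    if np.mean(mesh.face_normals[:, 2]) < 0:  # articular side faces proximally
        mesh = trimesh.Trimesh(mesh.vertices, mesh.faces[:, ::-1], process=False)
    return mesh


def make_implant_surfaces(spec: FixtureSpec | None = None) -> tuple[ImplantSurface, ImplantSurface]:
    """Generate the femoral and tibial articulating surfaces.

    Returns ``(femoral, tibial)``.  Both meshes are sagittally symmetric
    by construction; resolutions yielding fewer than 500 faces per
    component are rejected as too coarse for the contact quadrature.
    """
    spec = spec or FixtureSpec()
    femoral = trimesh.util.concatenate([_condyle_patch(spec, +1.0), _condyle_patch(spec, -1.0)])
    tibial = trimesh.util.concatenate([_dish_patch(spec, +1.0), _dish_patch(spec, -1.0)])
    for name, mesh in (("femoral", femoral), ("tibial", tibial)):
        if len(mesh.faces) < 500:
            raise ValueError(
                f"{name} mesh resolution too coarse ({len(mesh.faces)} faces < 500); increase resolution"
            )
    return ImplantSurface(femoral, "femoral"), ImplantSurface(tibial, "tibial")


def nominal_reference_pose(spec: FixtureSpec | None = None) -> JointPose:
    """Design pose at which the ligament reference strains are defined.

    Full extension with the dish bottoms a fraction of a millimetre into
    the condyles, i.e. the neighbourhood of the 0-degree equilibrium.
    """
    spec = spec or FixtureSpec()
    return JointPose(flexion=0.0, dp=-(spec.condyle_sagittal_radius - 0.25))


# ---------------------------------------------------------------------------
# Ligament fixture table
#
# Columns: name, femoral origin (x, y, z) mm, tibial insertion (x, y, z) mm,
# stiffness k (N per unit strain), reference strain at the nominal pose.
# Medial is +y, lateral is -y, anterior +x, proximal +z.  The tibial frame
# origin sits ~25 mm distal to the femoral origin at the nominal pose.
#
# Placement rationale (fixture stand-ins, not published data):
# * collaterals and deep MCL attach close to the gimbal axis (z ~ 0), so
#   they are near-isometric over flexion and carry a persistent load;
# * posterior capsule structures (opMCL, OPL, APL, mpCAP, lpCAP) attach
#   posterior-distal on the femur and on the posterior tibial rim: taut in
#   extension, slackening rapidly with flexion;
# * the two PCL bundles run from the posterior-distal notch to the
#   posterior tibia below the plateau; slack near extension, engaging and
#   tightening monotonically with flexion.
# ---------------------------------------------------------------------------
_LIGAMENT_TABLE: list[tuple[str, tuple[float, float, float], tuple[float, float, float], float, float]] = [
    # posterior cruciate (2 bundles): origins near the gimbal axis in the
    # notch so engagement is gradual; slack at extension
    ("PCL_am", (-1.95, 4.0, -3.9), (-22.0, 2.0, -8.0), 2600.0, -0.07),
    ("PCL_pl", (-2.6, -1.0, -5.2), (-23.0, -3.0, -10.0), 2000.0, -0.085),
    # medial collateral (3 bundles), near-isometric
    ("MCL_a", (4.0, 33.0, 1.0), (8.0, 30.0, -55.0), 2750.0, 0.045),
    ("MCL_c", (0.0, 34.0, 1.5), (2.0, 31.0, -58.0), 2750.0, 0.05),
    ("MCL_p", (-4.0, 33.0, 1.0), (-4.0, 30.0, -52.0), 2750.0, 0.04),
    # lateral collateral (3 bundles)
    ("LCL_a", (4.0, -33.0, 1.0), (7.0, -31.0, -48.0), 2000.0, 0.045),
    ("LCL_c", (0.0, -34.0, 1.5), (1.0, -32.0, -50.0), 2000.0, 0.05),
    ("LCL_p", (-4.0, -33.0, 1.0), (-5.0, -31.0, -46.0), 2000.0, 0.04),
    # oblique posterior MCL: posterior-medial capsule corner
    ("opMCL", (-14.0, 26.0, 4.0), (-22.0, 18.0, -14.0), 1800.0, 0.09),
    # deep MCL (2 bundles), short, near plateau rim
    ("dMCL_a", (2.0, 32.0, -1.0), (4.0, 30.0, -18.0), 1500.0, 0.035),
    ("dMCL_p", (-3.0, 32.0, -2.0), (-6.0, 30.0, -18.0), 1500.0, 0.03),
    # oblique popliteal (2 bundles), posterior capsule; femoral origins
    # posterior-proximal so the bundles fold slack as flexion proceeds
    ("OPL_m", (-16.0, 10.0, 5.0), (-24.0, 4.0, -12.0), 2200.0, 0.10),
    ("OPL_l", (-16.0, -6.0, 5.0), (-24.0, -10.0, -12.0), 2200.0, 0.10),
    # arcuate popliteal, posterior-lateral
    ("APL", (-15.0, -20.0, 4.0), (-22.0, -24.0, -13.0), 1800.0, 0.09),
    # posterior capsule, medial and lateral
    ("mpCAP", (-17.0, 16.0, 6.0), (-25.0, 12.0, -10.0), 2000.0, 0.10),
    ("lpCAP", (-17.0, -14.0, 6.0), (-25.0, -16.0, -10.0), 2000.0, 0.10),
]


def make_ligament_set(variant: str = "default", seed: int = 0, jitter_mm: float = 0.0) -> LigamentApparatus:
    """Build the 16-bundle ligament apparatus of the synthetic knee.

    Bundle census by prefix: PCL 2, MCL 3, LCL 3, opMCL 1, dMCL 2, OPL 2,
    APL 1, mpCAP 1, lpCAP 1.  ``jitter_mm`` adds seeded uniform jitter to
    every insertion coordinate for robustness studies (default 0: exact,
    reproducible coordinates).  Bundles are returned uncalibrated; rest
    lengths are set at the reference configuration.
    """
    if variant != "default":
        raise ValueError(f"unknown ligament-set variant {variant!r}")
    rng = np.random.default_rng(seed)
    bundles = []
    for name, origin, insertion, k, eps_r in _LIGAMENT_TABLE:
        o = np.array(origin, dtype=float)
        i = np.array(insertion, dtype=float)
        if jitter_mm > 0.0:
            o = o + rng.uniform(-jitter_mm, jitter_mm, 3)
            i = i + rng.uniform(-jitter_mm, jitter_mm, 3)
        bundles.append(
            LigamentBundle(name=name, origin=o, insertion=i, stiffness_k=k, reference_strain=eps_r)
        )
    return LigamentApparatus(bundles)


def make_exemplary_lcl_fixture() -> LigamentBundle:
    """The single vertical lateral-collateral bundle of the bench fixture.

    Stiffness 3300 N per unit strain, 11 % reference strain, transition to
    linear behaviour at 6 % strain.  The insertion points lie on a vertical
    line so that ligament elongation equals the relative vertical
    displacement of the mounting points.  The rest length is the fixture
    constant :data:`EXEMPLARY_LCL_REST_LENGTH_MM`; the reference
    insertion-point distance is ``L0 * 1.11 = 51.615 mm``.
    """
    l0 = EXEMPLARY_LCL_REST_LENGTH_MM
    eps_r = 0.11
    return LigamentBundle(
        name="LCL_exemplary",
        origin=np.zeros(3),
        insertion=np.array([0.0, 0.0, -l0 * (1.0 + eps_r)]),
        stiffness_k=3300.0,
        reference_strain=eps_r,
        rest_length=l0,
    )


def default_compliance_anchors() -> dict:
    """Measured 0-degree compliance anchors plus placeholder angle scales.

    0.7 mm unsensed deflection at 500 N with a 0.6 mm / 1000 N gradient
    beyond; the non-zero arm angles carry configurable placeholder scale
    factors (their curves were measured but only the 0-degree values are
    reported numerically).
    """
    return {
        "break_load_N": 500.0,
        "break_displacement_mm": 0.7,
        "linear_slope_mm_per_N": 0.0006,
        "angle_scale": dict(DEFAULT_ANGLE_SCALE),
    }


def default_compliance_curve() -> ComplianceCurve:
    """Compliance curve calibrated from :func:`default_compliance_anchors`."""
    a = default_compliance_anchors()
    return ComplianceCurve(
        break_load=a["break_load_N"],
        break_displacement=a["break_displacement_mm"],
        linear_slope=a["linear_slope_mm_per_N"],
        angle_scale=a["angle_scale"],
    )
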