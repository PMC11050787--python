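"""Joint-simulator emulation with unsensed actuator compliance.

The machine computes virtual ligament forces from its *sensed* joint
coordinates.  Under axial contact load the upper actuator deflects
elastically by ``s(F)``; the sensors do not register this, so the sensed
relative pose sits proximally of the true pose by ``s(F) - s_ref``, where
``s_ref`` is the deflection frozen in when the reference configuration was
set under the chosen preload.  Ligament insertion distances computed from
the sensed pose are therefore too short whenever the running contact force
exceeds the preload (and too long below it), corrupting the applied
ligament forces.  Contact, in contrast, acts at the true pose.

The servo/iterative-learning control loop of the physical machine is
idealized as exact quasi-static equilibrium at every flexion step; the
converged averaged cycles the hardware reports are the quantity this
emulation computes directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from ._equilibrium import EquilibriumResult, solve_free_dofs
from .compliance import ComplianceCurve
from .contact import ContactEngine, ContactLaw, ImplantSurface
from .kinematics import JointPose, pose_to_transform
from .ligaments import LigamentApparatus, LigamentBundle, force_from_strain
from .results import FlexionResult, run_schedule

__all__ = [
    "ReferenceConfiguration",
    "FlexionProtocol",
    "set_reference_configuration",
    "sensed_pose_from_true",
    "worked_example_force_vs_load",
    "solve_step_equilibrium",
    "run_passive_flexion",
]

_DEFLECTION_FP_TOL_MM = 1e-4
_DEFLECTION_FP_RELAX = 0.5
_DEFLECTION_FP_MAX_ITER = 50


@dataclass(frozen=True)
class ReferenceConfiguration:
    """Frozen state set before a test: pose, preload, insertion points.

    ``reference_deflection`` is the unsensed actuator deflection at the
    preload; during the test the sensed pose is shifted by
    ``s(F) - reference_deflection``, so the corruption vanishes exactly
    when the running contact force equals the preload.
    """

    reference_pose: JointPose
    preload: float  # N
    reference_deflection: float  # mm
    apparatus: LigamentApparatus  # calibrated at the reference pose
    compliance_curve: ComplianceCurve


@dataclass(frozen=True)
class FlexionProtocol:
    """Prescribed flexion schedule; the other five DOFs are force-controlled."""

    schedule: tuple[float, ...] = tuple(float(a) for a in range(0, 81))
    preload: float = 800.0  # N

    def __post_init__(self) -> None:
        s = self.schedule
        if any(b - a <= 0 for a, b in zip(s, s[1:])):
            raise ValueError("flexion schedule must be strictly increasing")
        if any(b - a > 2.0 + 1e-12 for a, b in zip(s, s[1:])):
            raise ValueError("flexion step must not exceed 2 degrees")
        if self.preload < 0:
            raise ValueError("preload must be nonnegative")


def set_reference_configuration(
    reference_pose: JointPose,
    preload: float,
    compliance_curve: ComplianceCurve,
    ligament_definitions: LigamentApparatus,
) -> ReferenceConfiguration:
    """Set the reference configuration under a chosen preload.

    Rest lengths of all bundles are calibrated from the insertion-point
    distances at the reference pose; the preload's deflection is stored so
    the sensed-pose corruption is zero at that contact force.  Preloading
    with the mean cycle load is the approximate compensation procedure.
    """
    if preload < 0:
        raise ValueError("preload must be nonnegative")
    apparatus = ligament_definitions.copy().calibrate(pose_to_transform(reference_pose))
    delta_ref = float(compliance_curve.displacement_at_load(preload, 0.0))
    return ReferenceConfiguration(
        reference_pose=reference_pose,
        preload=float(preload),
        reference_deflection=delta_ref,
        apparatus=apparatus,
        compliance_curve=compliance_curve,
    )


def sensed_pose_from_true(
    true_pose: JointPose,
    contact_axial_force: float,
    compliance_curve: ComplianceCurve,
    reference_deflection: float = 0.0,
) -> JointPose:
    """Pose the machine believes it is in, given the true pose.

    Differs from the true pose only by a distal-proximal shift of
    ``s(F) - s_ref``: the unsensed deflection moves the components
    together while the sensors read an unchanged gap.
    """
    if contact_axial_force < 0:
        contact_axial_force = 0.0
    shift = float(compliance_curve.displacement_at_load(contact_axial_force, 0.0)) - reference_deflection
    return dc_replace(true_pose, dp=true_pose.dp + shift)


def worked_example_force_vs_load(
    exemplary_bundle: LigamentBundle,
    compliance_curve: ComplianceCurve,
    load_grid: np.ndarray,
) -> pd.DataFrame:
    """Sensed force of the vertical bench-fixture ligament vs vertical load.

    The bundle hangs on a vertical line between the rigid test blocks, so
    its sensed elongation shrinks one-for-one with the unsensed deflection
    ``s1(F)`` (no preload compensation: ``s_ref = 0``).  Returns columns
    ``load_N``, ``s1_mm``, ``sensed_force_N``.
    """
    if exemplary_bundle.rest_length is None:
        raise ValueError("exemplary bundle must carry a rest length")
    loads = np.asarray(load_grid, dtype=float)
    s1 = np.asarray(compliance_curve.displacement_at_load(loads, 0.0), dtype=float)
    ref_distance = exemplary_bundle.rest_length * (1.0 + exemplary_bundle.reference_strain)
    length = ref_distance - s1
    strain = length / exemplary_bundle.rest_length - 1.0
    force = np.array(
        [
            force_from_strain(e, exemplary_bundle.stiffness_k, exemplary_bundle.linear_limit)
            for e in strain
        ]
    )
    return pd.DataFrame({"load_N": loads, "s1_mm": s1, "sensed_force_N": force})


def _emulator_wrench_fn(config: ReferenceConfiguration, engine: ContactEngine, shift_mm: float, prev_transform):
    """Contact at the true pose + ligaments at the sensed pose.

    The sensed pose is the true pose shifted proximally by ``shift_mm``.
    The machine applies the ligament resultant it computed from sensed
    geometry; its moments are transferred to the true tibial origin.
    """

    def fn(transform):
        ref = transform.translation
        slip = None
        if prev_transform is not None:
            slip = transform.apply(engine._samples_t) - prev_transform.apply(engine._samples_t)
        cw, _, _ = engine.wrench(transform, relative_slip=slip, moment_reference_point=ref)
        # sensed transform: dp shift along the tibial mechanical axis
        shift_vec = transform.rotation[:, 2] * shift_mm
        sensed = type(transform)(transform.rotation, transform.translation + shift_vec)
        lw = config.apparatus.wrench(sensed, moment_reference_point=ref)
        return cw + lw

    return fn


def solve_step_equilibrium(
    flexion_deg: float,
    previous_pose: JointPose,
    config: ReferenceConfiguration,
    engine: ContactEngine,
    prev_transform=None,
    deflection_init: float | None = None,
) -> tuple[EquilibriumResult, dict]:
    """One flexion step: equilibrium coupled to the unsensed deflection.

    Successive substitution (under-relaxation 0.5) between the axial
    contact force and the deflection ``s(F)``: the 5-DOF equilibrium is
    solved with the sensed-pose shift frozen, the resulting axial force
    updates the deflection, until the deflection changes by less than
    1e-4 mm.
    """
    curve = config.compliance_curve
    delta = float(deflection_init) if deflection_init is not None else config.reference_deflection
    pose = previous_pose
    res = None
    for _ in range(_DEFLECTION_FP_MAX_ITER):
        shift = delta - config.reference_deflection
        fn = _emulator_wrench_fn(config, engine, shift, prev_transform)
        probe = lambda t: engine.penetration(t).contact_count > 0
        res = solve_free_dofs(flexion_deg, pose, fn, contact_probe=probe)
        pose = res.pose
        transform = pose_to_transform(pose)
        _, axial, _ = engine.wrench(transform, moment_reference_point=transform.translation)
        delta_new = float(curve.displacement_at_load(max(axial, 0.0), 0.0))
        change = delta_new - delta
        delta += _DEFLECTION_FP_RELAX * change
        if abs(change) <= _DEFLECTION_FP_TOL_MM:
            break
    transform = pose_to_transform(pose)
    slip = None
    if prev_transform is not None:
        slip = transform.apply(engine._samples_t) - prev_transform.apply(engine._samples_t)
    _, axial, fld = engine.wrench(transform, relative_slip=slip, moment_reference_point=transform.translation)
    shift = delta - config.reference_deflection
    sensed_transform = type(transform)(transform.rotation, transform.translation + transform.rotation[:, 2] * shift)
    extras = {
        "axial_force_N": axial,
        "bundle_forces_true": config.apparatus.forces(transform),
        "bundle_forces_sensed": config.apparatus.forces(sensed_transform),
        "max_depth_mm": fld.max_depth,
        "contact_count": fld.contact_count,
        "deflection_mm": delta,
        "sensed_shift_mm": shift,
    }
    return res, extras


def run_passive_flexion(
    protocol: FlexionProtocol,
    config: ReferenceConfiguration,
    engine: ContactEngine,
) -> FlexionResult:
    """Emulated passive-flexion test under the given protocol.

    Warm-starts every step from the previous solution; kinematic outputs
    are expressed relative to the reference configuration at 0 degrees.
    """

    def step(flexion, warm_pose, state):
        prev_transform, delta_prev = state if state is not None else (None, None)
        res, extras = solve_step_equilibrium(
            flexion, warm_pose, config, engine, prev_transform, delta_prev
        )
        return res, extras, (pose_to_transform(res.pose), extras["deflection_mm"])

    records, aborted = run_schedule(list(protocol.schedule), step, config.reference_pose)
    from .reference_model import _records_to_result

    meta = {
        "model": "emulator",
        "preload_N": config.preload,
        "reference_deflection_mm": config.reference_deflection,
        "friction_mu": engine.law.friction_mu,
        "foundation_modulus_N_mm3": engine.law.foundation_modulus,
        "reference_pose": config.reference_pose.as_array().tolist(),
    }
    return _records_to_result(records, aborted, config.reference_pose, meta)
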