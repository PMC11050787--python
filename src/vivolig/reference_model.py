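"""Ground-truth quasi-static knee model (multibody-simulation analogue).

The femoral component is fixed; the tibial component carries the ligament
and contact wrenches at its *true* pose.  Flexion is prescribed
(rheonomic); the remaining five DOFs settle into static equilibrium at
every flexion angle.  Segment weights are neglected: the passive-flexion
load case is driven purely by the ligament-contact balance.

This model plays the role of the reference simulation against which the
compliance-corrupted simulator emulation is compared, and hosts the
virtual PCL-resection parameter sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._equilibrium import EquilibriumResult, solve_free_dofs
from .contact import ContactEngine, ContactLaw, ImplantSurface
from .kinematics import JointPose, pose_to_transform
from .ligaments import LigamentApparatus
from .results import FlexionResult, run_schedule

__all__ = [
    "ReferenceRunSpec",
    "solve_reference_equilibrium",
    "find_reference_state",
    "run_reference_flexion",
    "run_pcl_sweep",
]


@dataclass
class ReferenceRunSpec:
    """Inputs of one reference-model passive-flexion run."""

    schedule: list[float]
    apparatus: LigamentApparatus
    tibial_surface: ImplantSurface
    femoral_surface: ImplantSurface
    contact_law: ContactLaw = field(default_factory=ContactLaw)
    pcl_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pcl_scale <= 1.0:
            raise ValueError("pcl_scale must lie in [0, 1]")


def _total_wrench_fn(apparatus, engine, prev_transform):
    """Wrench on the tibia: true-pose contact + true-pose ligaments.

    Moments about the current tibial origin.  ``prev_transform`` (the last
    accepted step) supplies the slip direction for regularized friction;
    None means a frictionless solve (first step).
    """

    def fn(transform):
        slip = None
        if prev_transform is not None:
            slip = transform.apply(engine._samples_t) - prev_transform.apply(engine._samples_t)
        ref = transform.translation
        cw, _, _ = engine.wrench(transform, relative_slip=slip, moment_reference_point=ref)
        lw = apparatus.wrench(transform, moment_reference_point=ref)
        return cw + lw

    return fn


def solve_reference_equilibrium(
    flexion_deg: float,
    apparatus: LigamentApparatus,
    engine: ContactEngine,
    initial_pose: JointPose,
    prev_transform=None,
) -> tuple[EquilibriumResult, dict]:
    """Equilibrium of the five free DOFs at one prescribed flexion angle.

    Returns the solver result plus a record dict (axial force, per-bundle
    forces, contact diagnostics).
    """
    fn = _total_wrench_fn(apparatus, engine, prev_transform)
    probe = lambda t: engine.penetration(t).contact_count > 0
    res = solve_free_dofs(flexion_deg, initial_pose, fn, contact_probe=probe)
    transform = pose_to_transform(res.pose)
    slip = None
    if prev_transform is not None:
        slip = transform.apply(engine._samples_t) - prev_transform.apply(engine._samples_t)
    _, axial, fld = engine.wrench(transform, relative_slip=slip, moment_reference_point=transform.translation)
    extras = {
        "axial_force_N": axial,
        "bundle_forces_true": apparatus.forces(transform),
        "max_depth_mm": fld.max_depth,
        "contact_count": fld.contact_count,
        "deflection_mm": 0.0,
    }
    extras["bundle_forces_sensed"] = extras["bundle_forces_true"]
    return res, extras


def find_reference_state(
    apparatus: LigamentApparatus,
    engine: ContactEngine,
    nominal_pose: JointPose,
    n_pass: int = 3,
) -> tuple[JointPose, LigamentApparatus]:
    """Self-consistent 0-degree reference configuration.

    The ligament reference strains are defined at the reference
    configuration, which is itself the 0-degree equilibrium: calibrate at
    the nominal fixture pose, solve, re-calibrate at the solution and
    repeat.  Converges in 2-3 passes (pose changes become sub-micron).

    Returns the reference pose and the calibrated apparatus.
    """
    apparatus = apparatus.copy()
    pose = nominal_pose
    for _ in range(n_pass):
        apparatus.calibrate(pose_to_transform(pose))
        res, _ = solve_reference_equilibrium(0.0, apparatus, engine, pose)
        if not res.converged:
            raise RuntimeError(f"reference configuration did not converge: {res.message}")
        pose = res.pose
    apparatus.calibrate(pose_to_transform(pose))
    return pose, apparatus


def _records_to_result(records, aborted, reference_pose, meta) -> FlexionResult:
    rows, bft, bfs = [], [], []
    ap_ref = reference_pose.ap
    ir_ref = reference_pose.internal_rotation
    for flexion, res, extras in records:
        p = res.pose
        rows.append(
            {
                "flexion_deg": flexion,
                "axial_force_N": extras["axial_force_N"],
                "tibial_ie_deg": p.internal_rotation - ir_ref,
                "femoral_ap_mm": -(p.ap - ap_ref),
                "adduction_deg": p.adduction,
                "ap_mm": p.ap,
                "ml_mm": p.ml,
                "dp_mm": p.dp,
                "deflection_mm": extras["deflection_mm"],
                "total_lig_force_true_N": sum(extras["bundle_forces_true"].values()),
                "total_lig_force_sensed_N": sum(extras["bundle_forces_sensed"].values()),
                "residual_force_N": res.residual_force_N,
                "residual_moment_Nmm": res.residual_moment_Nmm,
                "converged": res.converged,
                "in_contact": res.in_contact,
            }
        )
        bft.append({"flexion_deg": flexion, **extras["bundle_forces_true"]})
        bfs.append({"flexion_deg": flexion, **extras["bundle_forces_sensed"]})
    return FlexionResult(
        table=pd.DataFrame(rows),
        bundle_forces_true=pd.DataFrame(bft),
        bundle_forces_sensed=pd.DataFrame(bfs),
        meta=meta,
        aborted=aborted,
    )


def run_reference_flexion(
    spec: ReferenceRunSpec,
    reference_pose: JointPose | None = None,
    nominal_pose: JointPose | None = None,
) -> FlexionResult:
    """Passive-flexion sweep of the reference model.

    If ``reference_pose`` is None the self-consistent reference state is
    found first (requires ``nominal_pose`` as the starting guess).  The
    apparatus is re-calibrated at the reference pose; PCL scaling is
    applied after calibration, so resection never changes rest lengths.
    """
    engine = ContactEngine(spec.tibial_surface, spec.femoral_surface, spec.contact_law)
    if reference_pose is None:
        if nominal_pose is None:
            raise ValueError("provide reference_pose or nominal_pose")
        reference_pose, apparatus = find_reference_state(spec.apparatus, engine, nominal_pose)
    else:
        apparatus = spec.apparatus.copy().calibrate(pose_to_transform(reference_pose))
    if spec.pcl_scale != 1.0:
        apparatus.set_resection("PCL", spec.pcl_scale)

    def step(flexion, warm_pose, state):
        prev_transform = state
        res, extras = solve_reference_equilibrium(flexion, apparatus, engine, warm_pose, prev_transform)
        return res, extras, pose_to_transform(res.pose)

    records, aborted = run_schedule(spec.schedule, step, reference_pose)
    meta = {
        "model": "reference",
        "pcl_scale": spec.pcl_scale,
        "friction_mu": spec.contact_law.friction_mu,
        "foundation_modulus_N_mm3": spec.contact_law.foundation_modulus,
        "reference_pose": reference_pose.as_array().tolist(),
    }
    return _records_to_result(records, aborted, reference_pose, meta)


def run_pcl_sweep(
    spec_base: ReferenceRunSpec,
    scales=(1.0, 0.5, 0.25, 0.0),
    nominal_pose: JointPose | None = None,
) -> list[FlexionResult]:
    """Virtual PCL resection: one reference run per stiffness scale.

    All other parameters (geometry, other ligaments, reference
    configuration, contact law) are bit-identical across runs; resection
    only rescales the stiffness of the PCL bundles, applied after rest
    lengths are calibrated at the shared reference configuration.
    """
    if nominal_pose is None:
        from .synthdata import nominal_reference_pose

        nominal_pose = nominal_reference_pose()
    engine = ContactEngine(spec_base.tibial_surface, spec_base.femoral_surface, spec_base.contact_law)
    reference_pose, _ = find_reference_state(spec_base.apparatus, engine, nominal_pose)
    results = []
    for s in scales:
        run_spec = replace(spec_base, pcl_scale=float(s))
        results.append(run_reference_flexion(run_spec, reference_pose=reference_pose))
    return results
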