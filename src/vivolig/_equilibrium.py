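"""Quasi-static equilibrium core shared by the reference model and emulator.

Flexion is position-controlled (prescribed); the remaining five joint
coordinates (adduction, internal rotation, AP, ML, DP) are force-controlled
and settle where the generalized forces of the total wrench on the tibial
component vanish.

Generalized forces are computed by virtual work: for each free coordinate
the kinematic Jacobian of the tibial frame (translation velocity of the
tibial origin plus angular velocity) is obtained by central differences on
the pose-to-transform map, and contracted with the wrench taken about the
current tibial origin.  The resulting 5-vector residual mixes forces (N)
and torques (N*mm); torques are scaled by a characteristic length so a
single damped-Newton iteration handles both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .kinematics import JointPose, RigidTransform, pose_to_transform

__all__ = ["EquilibriumResult", "solve_free_dofs", "generalized_forces"]

#: Convergence tolerances on the free-DOF generalized forces.
FORCE_TOL_N = 0.5
MOMENT_TOL_NMM = 50.0

_MOMENT_SCALE_MM = 100.0  # torque (N*mm) -> equivalent force residual (N)
_JAC_STEP = 1e-3  # central-difference step, mm and deg


@dataclass
class EquilibriumResult:
    pose: JointPose
    converged: bool
    iterations: int
    residual_force_N: float
    residual_moment_Nmm: float
    in_contact: bool
    message: str = ""


def _pose_jacobian(pose: JointPose) -> tuple[np.ndarray, np.ndarray]:
    """Twist of the tibial frame per unit free coordinate.

    Returns ``(v, omega)`` with shapes (5, 3): translation velocity of the
    tibial origin (mm per mm-or-deg) and angular velocity (rad per
    mm-or-deg) for each of the five force-controlled coordinates.
    """
    q0 = pose.free_array()
    v = np.zeros((5, 3))
    omega = np.zeros((5, 3))
    for i in range(5):
        qp, qm = q0.copy(), q0.copy()
        qp[i] += _JAC_STEP
        qm[i] -= _JAC_STEP
        tp = pose_to_transform(pose.with_free(qp))
        tm = pose_to_transform(pose.with_free(qm))
        v[i] = (tp.translation - tm.translation) / (2.0 * _JAC_STEP)
        dr = (tp.rotation - tm.rotation) / (2.0 * _JAC_STEP)
        w = dr @ pose_to_transform(pose).rotation.T
        omega[i] = np.array([w[2, 1], w[0, 2], w[1, 0]])
    return v, omega


def generalized_forces(pose: JointPose, wrench_fn: Callable[[RigidTransform], np.ndarray]) -> np.ndarray:
    """Generalized forces Q on the five free coordinates.

    ``wrench_fn`` must return the total 6-vector wrench (force N, moment
    N*mm) on the tibial component with moments taken about the current
    tibial origin, given the tibia-to-femur transform.
    """
    transform = pose_to_transform(pose)
    w = wrench_fn(transform)
    v, omega = _pose_jacobian(pose)
    return v @ w[:3] + omega @ w[3:]


def _residual(pose: JointPose, wrench_fn) -> np.ndarray:
    """Scaled residual: translations in N, rotations in N*mm/scale."""
    q = generalized_forces(pose, wrench_fn)
    r = q.copy()
    deg = np.pi / 180.0
    # rotational coordinates (adduction, internal rotation) are in degrees;
    # their generalized force is N*mm*rad/deg -> convert to N*mm, then scale
    r[:2] = (q[:2] / deg) / _MOMENT_SCALE_MM
    return r


def solve_free_dofs(
    flexion_deg: float,
    initial_pose: JointPose,
    wrench_fn: Callable[[RigidTransform], np.ndarray],
    contact_probe: Callable[[RigidTransform], bool] | None = None,
    max_iter: int = 60,
) -> EquilibriumResult:
    """Damped Newton / Levenberg least-squares solve of the 5 free DOFs.

    The Jacobian is built by central differences (step 1e-3 mm / deg) on
    the scaled residual; steps are backtracked until the residual norm
    decreases.  Convergence requires the generalized forces to fall below
    0.5 N (translations) and 50 N*mm (rotations).
    """
    pose = JointPose(flexion=flexion_deg).with_free(initial_pose.free_array())
    r = _residual(pose, wrench_fn)
    it = 0
    for it in range(1, max_iter + 1):
        if _converged(r):
            break
        q0 = pose.free_array()
        jac = np.zeros((5, 5))
        h = 1e-3
        for i in range(5):
            qp, qm = q0.copy(), q0.copy()
            qp[i] += h
            qm[i] -= h
            rp = _residual(pose.with_free(qp), wrench_fn)
            rm = _residual(pose.with_free(qm), wrench_fn)
            jac[:, i] = (rp - rm) / (2.0 * h)
        step = np.linalg.lstsq(jac, -r, rcond=None)[0]
        # cap the step so contact sampling stays in its smooth regime
        cap = np.max(np.abs(step)) / 2.0
        if cap > 1.0:
            step = step / cap
        accepted = False
        for damp in (1.0, 0.5, 0.25, 0.1, 0.05, 0.02, 0.005):
            cand = pose.with_free(q0 + damp * step)
            rc = _residual(cand, wrench_fn)
            if np.linalg.norm(rc) < np.linalg.norm(r):
                pose, r = cand, rc
                accepted = True
                break
        if not accepted:
            # no productive step along the Newton direction
            break
    q = generalized_forces(pose, wrench_fn)
    deg = np.pi / 180.0
    res_f = float(np.max(np.abs(q[2:])))
    res_m = float(np.max(np.abs(q[:2] / deg)))
    in_contact = True if contact_probe is None else bool(contact_probe(pose_to_transform(pose)))
    ok = res_f <= FORCE_TOL_N and res_m <= MOMENT_TOL_NMM
    msg = "" if ok else f"not converged after {it} iterations (|F|={res_f:.3g} N, |M|={res_m:.3g} N*mm)"
    if not in_contact:
        msg = (msg + "; " if msg else "") + "loss of contact: solved with zero contact wrench"
    return EquilibriumResult(pose, ok, it, res_f, res_m, in_contact, msg)


def _converged(r: np.ndarray) -> bool:
    return (
        np.max(np.abs(r[2:])) <= FORCE_TOL_N * 0.5
        and np.max(np.abs(r[:2])) * _MOMENT_SCALE_MM <= MOMENT_TOL_NMM * 0.5
    )
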