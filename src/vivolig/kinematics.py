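"""Six-coordinate tibiofemoral pose representation and rigid transforms.

Frame conventions (right knee):

* **Femoral frame** — fixed in the femoral component, origin on the gimbal
  flexion axis at the mid-condylar point. ``x`` anterior, ``y`` medial,
  ``z`` proximal; right-handed.
* **Tibial frame** — fixed in the tibial component, origin at the centre of
  the tibial plateau on the mechanical tibial axis, which is orthogonal to
  the mounting plate.  Axes parallel to the femoral frame at the zero pose.

The six joint coordinates follow the Grood–Suntay joint-coordinate
convention: flexion about the femoral gimbal (medial–lateral) axis, then
adduction about the floating anterior axis, then internal rotation of the
tibia about its mechanical axis.  Translations (anterior, medial, proximal
positive) are the position of the tibial origin expressed along the rotated
tibial axes.  Angles are degrees externally, radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["JointPose", "RigidTransform", "pose_to_transform", "transform_to_pose", "transform_point"]


@dataclass(frozen=True)
class JointPose:
    """Pose of the tibial component relative to the femoral component.

    Angles in degrees, translations in mm.  ``flexion`` rotates the tibia
    posteriorly about the gimbal axis; ``adduction`` and
    ``internal_rotation`` are positive for a right knee per the
    anterior/medial/proximal-positive convention.
    """

    flexion: float = 0.0
    adduction: float = 0.0
    internal_rotation: float = 0.0
    ap: float = 0.0  # anterior translation, mm
    ml: float = 0.0  # medial translation, mm
    dp: float = 0.0  # proximal translation, mm

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.flexion, self.adduction, self.internal_rotation, self.ap, self.ml, self.dp],
            dtype=float,
        )

    @staticmethod
    def from_array(q: np.ndarray) -> "JointPose":
        q = np.asarray(q, dtype=float)
        return JointPose(*q.tolist())

    def with_free(self, free: np.ndarray) -> "JointPose":
        """Replace the five force-controlled coordinates (all but flexion)."""
        a, r, x, y, z = np.asarray(free, dtype=float).tolist()
        return replace(self, adduction=a, internal_rotation=r, ap=x, ml=y, dp=z)

    def free_array(self) -> np.ndarray:
        return np.array([self.adduction, self.internal_rotation, self.ap, self.ml, self.dp])


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation mapping tibial-frame points into the femoral frame."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def pose_to_transform(pose: JointPose) -> RigidTransform:
    """Rigid transform of the tibial frame w.r.t. the femoral frame.

    Rotation sequence: flexion about the femoral ``y`` (gimbal) axis,
    adduction about the floating ``x`` axis, internal rotation about the
    tibial ``z`` axis.  Positive flexion carries the distal tibia
    posteriorly (a rotation by ``+flexion`` about the medial ``+y`` axis
    of this right-knee frame).  Translations are expressed along the
    rotated tibial axes.
    """
    fl = np.deg2rad(pose.flexion)
    ad = np.deg2rad(pose.adduction)
    ir = np.deg2rad(pose.internal_rotation)
    rot = _rot_y(fl) @ _rot_x(ad) @ _rot_z(ir)
    t_local = np.array([pose.ap, pose.ml, pose.dp], dtype=float)
    return RigidTransform(rot, rot @ t_local)


def transform_to_pose(transform: RigidTransform) -> JointPose:
    """Recover joint coordinates from a rigid transform.

    Valid away from gimbal lock (|adduction| < 90 deg); the round trip with
    :func:`pose_to_transform` is exact to floating precision there.
    """
    r = transform.rotation
    fl, ad, ir = _euler_yxz_from_matrix(r)
    t_local = r.T @ transform.translation
    return JointPose(
        flexion=np.rad2deg(fl),
        adduction=np.rad2deg(ad),
        internal_rotation=np.rad2deg(ir),
        ap=t_local[0],
        ml=t_local[1],
        dp=t_local[2],
    )


def _euler_yxz_from_matrix(r: np.ndarray) -> tuple[float, float, float]:
    """Angles (flexion, adduction, internal) with R = Ry(fl) Rx(ad) Rz(ir)."""
    # Ry(b) Rx(a) Rz(g) with b = fl:
    # Ry(b)Rx(a)Rz(g) =
    # [ c_b c_g + s_b s_a s_g,  -c_b s_g + s_b s_a c_g,  s_b c_a ]
    # [ c_a s_g,                 c_a c_g,               -s_a     ]
    # [-s_b c_g + c_b s_a s_g,   s_b s_g + c_b s_a c_g,  c_b c_a ]
    a = np.arcsin(np.clip(-r[1, 2], -1.0, 1.0))
    b = np.arctan2(r[0, 2], r[2, 2])
    g = np.arctan2(r[1, 0], r[1, 1])
    return b, a, g


def transform_point(transform: RigidTransform, point: np.ndarray) -> np.ndarray:
    """Map a point (mm) through a rigid transform; an isometry."""
    return transform.apply(np.asarray(point, dtype=float))
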