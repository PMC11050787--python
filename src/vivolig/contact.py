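"""Elastic-foundation contact between articulating implant surfaces.

The articulating surfaces are triangle meshes: a convex bicondylar femoral
component and a matching dished tibial insert.  Contact is resolved with an
elastic-foundation (bed-of-springs) model: the tibial articular surface is
sampled at its face centroids, each sample carrying its face area; where a
sample point lies behind the femoral surface, a pressure proportional to
the penetration depth acts on its area along the femoral outward normal.

Tangential (frictional) tractions follow a regularized Coulomb law: the
traction opposes the relative slip of the tibial material and saturates at
``mu`` times the normal pressure, with a smooth ``tanh`` ramp over a
regularization slip scale so the quasi-static solver sees a C1 force field.

Closest-point queries are accelerated with a cKDTree over femoral triangle
centroids; candidate triangles are then resolved exactly with
``trimesh.triangles.closest_point``.  Ties are broken by the smallest face
index, making the field deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .kinematics import RigidTransform

__all__ = ["ImplantSurface", "ContactLaw", "ContactEngine", "penetration_field", "contact_wrench"]


@dataclass
class ImplantSurface:
    """Oriented articulating triangle mesh in an implant-fixed frame.

    ``frame`` is ``"femoral"`` or ``"tibial"``.  Outward normals point away
    from the implant material, i.e. toward the opposing component on the
    articular side.
    """

    mesh: trimesh.Trimesh
    frame: str

    def __post_init__(self) -> None:
        if self.frame not in ("femoral", "tibial"):
            raise ValueError(f"frame must be 'femoral' or 'tibial', got {self.frame!r}")
        if len(self.mesh.faces) == 0:
            raise ValueError("empty mesh")
        if np.any(self.mesh.area_faces <= 1e-12):
            raise ValueError("mesh contains degenerate faces")

    @staticmethod
    def from_file(path: str | Path, frame: str) -> "ImplantSurface":
        mesh = trimesh.load_mesh(str(path), process=False)
        return ImplantSurface(mesh, frame)

    def to_file(self, path: str | Path) -> None:
        self.mesh.export(str(path))


@dataclass(frozen=True)
class ContactLaw:
    """Elastic-foundation and regularized-friction parameters.

    ``foundation_modulus`` is pressure per unit penetration (N/mm^3), of
    the order of a UHMWPE elastic foundation; ``friction_mu`` the Coulomb
    coefficient; ``regularization_slip`` the slip (mm per quasi-static
    step) over which friction ramps to saturation.
    """

    foundation_modulus: float = 30.0  # N/mm^3
    friction_mu: float = 0.04
    regularization_slip: float = 0.05  # mm per step

    def __post_init__(self) -> None:
        if self.foundation_modulus <= 0:
            raise ValueError("foundation_modulus must be positive")
        if self.friction_mu < 0:
            raise ValueError("friction_mu must be nonnegative")
        if self.regularization_slip <= 0:
            raise ValueError("regularization_slip must be positive")


@dataclass
class PenetrationField:
    """Per-sample contact state, all in the femoral frame."""

    points: np.ndarray  # (n, 3) tibial sample points, femoral frame, mm
    depths: np.ndarray  # (n,) penetration depth, mm (0 where separated)
    normals: np.ndarray  # (n, 3) femoral outward normal at the closest point
    areas: np.ndarray  # (n,) sample areas, mm^2

    @property
    def max_depth(self) -> float:
        return float(self.depths.max(initial=0.0))

    @property
    def contact_count(self) -> int:
        return int(np.count_nonzero(self.depths > 0.0))


class ContactEngine:
    """Cached contact evaluator for one femoral/tibial surface pair.

    The femoral component is fixed in its own frame, so its triangle
    KD-tree is built once; per-pose evaluation only transforms the tibial
    sample points.
    """

    def __init__(
        self,
        tibial_surface: ImplantSurface,
        femoral_surface: ImplantSurface,
        law: ContactLaw | None = None,
        n_candidates: int = 8,
    ) -> None:
        self.law = law or ContactLaw()
        self._fem = femoral_surface.mesh
        self._tri = self._fem.triangles.view(np.ndarray)
        self._tri_normals = self._fem.face_normals.view(np.ndarray)
        self._tree = cKDTree(self._tri.mean(axis=1))
        self._k = min(n_candidates, len(self._fem.faces))
        tib = tibial_surface.mesh
        self._samples_t = tib.triangles_center.view(np.ndarray).copy()
        self._areas = tib.area_faces.view(np.ndarray).copy()
        # conservative bound on centroid-to-closest-point error per triangle
        self._tri_radius = np.linalg.norm(
            self._tri - self._tri.mean(axis=1, keepdims=True), axis=2
        ).max()

    def penetration(self, relative_transform: RigidTransform) -> PenetrationField:
        """Depth field at the tibial sample points for a given relative pose."""
        all_pts = relative_transform.apply(self._samples_t)
        # coarse cull: points farther from every femoral centroid than the
        # triangle radius plus a generous depth margin cannot penetrate
        d1, _ = self._tree.query(all_pts, k=1)
        near = d1 <= self._tri_radius + 3.0
        depths_all = np.zeros(len(all_pts))
        normals_all = np.zeros((len(all_pts), 3))
        if not np.any(near):
            return PenetrationField(all_pts, depths_all, normals_all, self._areas)
        pts = all_pts[near]
        dists, idx = self._tree.query(pts, k=self._k)
        idx = np.atleast_2d(idx)
        n, k = idx.shape
        # exact closest point on each candidate triangle
        flat_idx = idx.reshape(-1)
        tri = self._tri[flat_idx]
        rep = np.repeat(pts, k, axis=0)
        closest = trimesh.triangles.closest_point(tri, rep)
        d2 = np.einsum("ij,ij->i", rep - closest, rep - closest).reshape(n, k)
        # smallest distance wins; ties broken by smallest face index
        order = np.lexsort((idx, np.round(d2, 12)), axis=1)
        best = order[:, 0]
        rows = np.arange(n)
        face = idx[rows, best]
        q = closest.reshape(n, k, 3)[rows, best]
        normal = self._tri_normals[face]
        delta = pts - q
        dist = np.linalg.norm(delta, axis=1)
        inside = np.einsum("ij,ij->i", delta, normal) < 0.0
        depths_all[near] = np.where(inside, dist, 0.0)
        normals_all[near] = normal
        return PenetrationField(points=all_pts, depths=depths_all, normals=normals_all, areas=self._areas)

    def wrench(
        self,
        relative_transform: RigidTransform,
        relative_slip: np.ndarray | None = None,
        moment_reference_point: np.ndarray | tuple = (0.0, 0.0, 0.0),
    ) -> tuple[np.ndarray, float, PenetrationField]:
        """Contact wrench on the tibial component, femoral frame.

        Returns ``(wrench6, axial_force, field)`` where ``axial_force`` is
        the (positive-in-compression) contact force component along the
        tibial mechanical axis.  ``relative_slip`` is the motion of the
        tibial contact material relative to the femur over the last
        quasi-static step (3-vector, femoral frame, mm); friction opposes
        it.  The wrench on the femoral component is the exact negative.
        """
        field = self.penetration(relative_transform)
        law = self.law
        mask = field.depths > 0.0
        wrench = np.zeros(6)
        if np.any(mask):
            p = field.points[mask]
            n = field.normals[mask]
            fn_mag = law.foundation_modulus * field.depths[mask] * field.areas[mask]
            forces = fn_mag[:, None] * n
            wrench[:3] = forces.sum(axis=0)
            ref = np.asarray(moment_reference_point, dtype=float)
            wrench[3:] = np.cross(p - ref, forces).sum(axis=0)
            if relative_slip is not None and law.friction_mu > 0.0:
                slip = np.asarray(relative_slip, dtype=float)
                if slip.ndim == 1:
                    slip = np.broadcast_to(slip, p.shape)
                else:
                    slip = slip[mask]
                sn = np.einsum("ij,ij->i", slip, n)
                slip_t = slip - sn[:, None] * n
                mag = np.linalg.norm(slip_t, axis=1)
                nz = mag > 1e-12
                if np.any(nz):
                    scale = law.friction_mu * fn_mag[nz] * np.tanh(mag[nz] / law.regularization_slip)
                    ft = -(scale / mag[nz])[:, None] * slip_t[nz]
                    wrench[:3] += ft.sum(axis=0)
                    wrench[3:] += np.cross(p[nz] - ref, ft).sum(axis=0)
        axial_axis = relative_transform.rotation[:, 2]  # tibial mechanical axis, femoral frame
        axial_force = float(-wrench[:3] @ axial_axis)
        return wrench, axial_force, field


def penetration_field(
    tibial_surface: ImplantSurface,
    femoral_surface: ImplantSurface,
    relative_transform: RigidTransform,
) -> PenetrationField:
    """One-off penetration field; see :class:`ContactEngine.penetration`."""
    return ContactEngine(tibial_surface, femoral_surface).penetration(relative_transform)


def contact_wrench(
    tibial_surface: ImplantSurface,
    femoral_surface: ImplantSurface,
    relative_transform: RigidTransform,
    law: ContactLaw | None = None,
    relative_slip: np.ndarray | None = None,
    moment_reference_point: np.ndarray | tuple = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, float]:
    """One-off contact wrench on the tibial component; see :class:`ContactEngine`."""
    engine = ContactEngine(tibial_surface, femoral_surface, law)
    wrench, axial, _ = engine.wrench(relative_transform, relative_slip, moment_reference_point)
    return wrench, axial
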