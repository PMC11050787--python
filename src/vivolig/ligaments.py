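"""Virtual ligament bundles and the quadratic-to-linear force law.

Each ligament bundle is a tension-only nonlinear spring acting on the
straight line between an origin point fixed in the femoral-component frame
and an insertion point fixed in the tibial-component frame.  The force law
is the piecewise Wismans/Blankevoort form used throughout the knee-modelling
literature: with engineering strain ``eps = (L - L0)/L0``,

    f(eps) = 0                          eps <= 0          (slack)
    f(eps) = k * eps^2 / (4*eps_l)      0 < eps <= 2*eps_l (toe region)
    f(eps) = k * (eps - eps_l)          eps > 2*eps_l      (linear)

``k`` is the stiffness in N per unit strain and ``2*eps_l`` the transition
strain (default 0.06, i.e. linear beyond 6 % strain).  The two branches
share value and slope at ``2*eps_l``, so the law is C1.

Rest lengths are not specified directly: a bundle is calibrated by its
strain at a reference configuration, ``L0 = L_ref / (1 + eps_r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .kinematics import RigidTransform

__all__ = [
    "DEFAULT_TRANSITION_STRAIN",
    "LigamentBundle",
    "LigamentApparatus",
    "force_from_strain",
    "rest_length_from_reference",
]

#: Strain at which the force law becomes linear (2 * eps_l).
DEFAULT_TRANSITION_STRAIN = 0.06


class DegenerateBundleError(ValueError):
    """Raised when ligament insertion points coincide."""


class UncalibratedBundleError(RuntimeError):
    """Raised when a bundle force is requested before rest-length calibration."""


def force_from_strain(strain: float, stiffness_k: float, linear_limit: float | None = None) -> float:
    """Tensile force (N) of the nonlinear ligament law at a given strain.

    Parameters
    ----------
    strain
        Engineering strain, dimensionless; negative (slack) gives zero force.
    stiffness_k
        Stiffness in N per unit strain; must be positive.
    linear_limit
        ``eps_l``; the quadratic toe region ends at ``2 * eps_l``.  Defaults
        to half of :data:`DEFAULT_TRANSITION_STRAIN`.
    """
    if linear_limit is None:
        linear_limit = DEFAULT_TRANSITION_STRAIN / 2.0
    if stiffness_k <= 0:
        raise ValueError(f"stiffness_k must be positive, got {stiffness_k}")
    if linear_limit <= 0:
        raise ValueError(f"linear_limit must be positive, got {linear_limit}")
    eps = np.asarray(strain, dtype=float)
    quad = stiffness_k * eps**2 / (4.0 * linear_limit)
    lin = stiffness_k * (eps - linear_limit)
    out = np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * linear_limit, quad, lin))
    return float(out) if out.ndim == 0 else out


def rest_length_from_reference(
    origin_world: Sequence[float] | float,
    insertion_world: Sequence[float] | None = None,
    reference_strain: float = 0.0,
) -> float:
    """Rest length L0 (mm) from the insertion distance at the reference pose.

    ``L0 = L_ref / (1 + eps_r)``, so that re-evaluating the strain at the
    reference pose returns ``eps_r`` exactly.  Either pass the two world
    points, or a single scalar reference distance as ``origin_world``.
    """
    if insertion_world is None:
        dist = float(origin_world)
    else:
        dist = float(np.linalg.norm(np.asarray(origin_world, float) - np.asarray(insertion_world, float)))
    if reference_strain <= -1.0:
        raise ValueError(f"reference_strain must exceed -1, got {reference_strain}")
    if dist <= 0.0:
        raise DegenerateBundleError("coincident ligament insertion points (zero reference distance)")
    return dist / (1.0 + reference_strain)


@dataclass
class LigamentBundle:
    """One nonlinear elastic fiber between implant-fixed insertion points.

    ``origin`` lives in the femoral-component frame, ``insertion`` in the
    tibial-component frame (mm).  ``stiffness_scale`` in [0, 1] supports
    virtual resection; the applied force is ``scale * f(strain)``.
    """

    name: str
    origin: np.ndarray
    insertion: np.ndarray
    stiffness_k: float
    reference_strain: float
    linear_limit: float = DEFAULT_TRANSITION_STRAIN / 2.0
    rest_length: float | None = None
    stiffness_scale: float = 1.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.insertion = np.asarray(self.insertion, dtype=float)
        if self.stiffness_k <= 0:
            raise ValueError(f"{self.name}: stiffness_k must be positive")
        if self.linear_limit <= 0:
            raise ValueError(f"{self.name}: linear_limit must be positive")
        if not 0.0 <= self.stiffness_scale <= 1.0:
            raise ValueError(f"{self.name}: stiffness_scale must lie in [0, 1]")
        if self.rest_length is not None and self.rest_length <= 0:
            raise ValueError(f"{self.name}: rest_length must be positive")

    # -- calibration ---------------------------------------------------

    def calibrate(self, transform: RigidTransform) -> "LigamentBundle":
        """Set the rest length from the insertion distance at a reference pose.

        ``transform`` maps tibial-frame points into the femoral frame.
        """
        insertion_f = transform.apply(self.insertion)
        self.rest_length = rest_length_from_reference(
            self.origin, insertion_f, self.reference_strain
        )
        return self

    # -- evaluation ----------------------------------------------------

    def current_length(self, transform: RigidTransform) -> float:
        insertion_f = transform.apply(self.insertion)
        return float(np.linalg.norm(self.origin - insertion_f))

    def strain(self, transform: RigidTransform) -> float:
        if self.rest_length is None:
            raise UncalibratedBundleError(f"{self.name}: calibrate() before evaluating strain")
        return self.current_length(transform) / self.rest_length - 1.0

    def force_magnitude(self, transform: RigidTransform) -> float:
        """Scaled tensile force (N) at the current pose; zero when slack."""
        return self.stiffness_scale * force_from_strain(
            self.strain(transform), self.stiffness_k, self.linear_limit
        )

    def force_vector(self, transform: RigidTransform) -> tuple[np.ndarray, float]:
        """Force on the tibial insertion point, in the femoral frame.

        Returns ``(force_3vec_N, magnitude_N)``; the force pulls the
        insertion toward the origin (pure tension along the fiber line).
        """
        insertion_f = transform.apply(self.insertion)
        d = self.origin - insertion_f
        length = float(np.linalg.norm(d))
        if length <= 0.0:
            raise DegenerateBundleError(f"{self.name}: coincident points at current pose")
        mag = self.force_magnitude(transform)
        return mag / length * d, mag


@dataclass
class LigamentApparatus:
    """Ordered collection of uniquely named ligament bundles."""

    bundles: list[LigamentBundle] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [b.name for b in self.bundles]
        if len(set(names)) != len(names):
            raise ValueError("bundle names must be unique")

    def __iter__(self) -> Iterable[LigamentBundle]:
        return iter(self.bundles)

    def __len__(self) -> int:
        return len(self.bundles)

    def __getitem__(self, name: str) -> LigamentBundle:
        for b in self.bundles:
            if b.name == name:
                return b
        raise KeyError(name)

    def calibrate(self, transform: RigidTransform) -> "LigamentApparatus":
        for b in self.bundles:
            b.calibrate(transform)
        return self

    def wrench(
        self, transform: RigidTransform, moment_reference_point: Sequence[float] = (0.0, 0.0, 0.0)
    ) -> np.ndarray:
        """Resultant (force N, moment N·mm) of all bundles on the tibial component.

        Forces act at the tibial insertion points; moments are taken about
        ``moment_reference_point`` (femoral frame).  Returns a 6-vector
        ``[Fx, Fy, Fz, Mx, My, Mz]``.
        """
        ref = np.asarray(moment_reference_point, dtype=float)
        total = np.zeros(6)
        for b in self.bundles:
            f, _ = b.force_vector(transform)
            p = transform.apply(b.insertion)
            total[:3] += f
            total[3:] += np.cross(p - ref, f)
        return total

    def forces(self, transform: RigidTransform) -> dict[str, float]:
        """Per-bundle scaled force magnitudes (N) at a pose."""
        return {b.name: b.force_magnitude(transform) for b in self.bundles}

    def set_resection(self, bundle_name_prefix: str, scale: float) -> "LigamentApparatus":
        """Scale the stiffness of every bundle whose name starts with a prefix.

        Emulates virtual resection (e.g. prefix ``"PCL"`` with scale 0
        disables the posterior cruciate).  Raises if nothing matches, to
        guard parameter sweeps against silent no-ops.
        """
        if not 0.0 <= scale <= 1.0:
            raise ValueError(f"scale must lie in [0, 1], got {scale}")
        matched = [b for b in self.bundles if b.name.startswith(bundle_name_prefix)]
        if not matched:
            raise KeyError(f"no bundle matches prefix {bundle_name_prefix!r}")
        for b in matched:
            b.stiffness_scale = scale
        return self

    def copy(self) -> "LigamentApparatus":
        return LigamentApparatus([replace(b, origin=b.origin.copy(), insertion=b.insertion.copy()) for b in self.bundles])

    # -- serialization -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = [
            {
                "name": b.name,
                "origin_mm": [float(v) for v in b.origin],
                "insertion_mm": [float(v) for v in b.insertion],
                "stiffness_N_per_strain": float(b.stiffness_k),
                "reference_strain": float(b.reference_strain),
                "linear_limit": float(b.linear_limit),
                "stiffness_scale": float(b.stiffness_scale),
            }
            for b in self.bundles
        ]
        Path(path).write_text(yaml.safe_dump({"bundles": data}, sort_keys=False))

    @staticmethod
    def from_yaml(path: str | Path) -> "LigamentApparatus":
        data = yaml.safe_load(Path(path).read_text())
        bundles = [
            LigamentBundle(
                name=d["name"],
                origin=d["origin_mm"],
                insertion=d["insertion_mm"],
                stiffness_k=d["stiffness_N_per_strain"],
                reference_strain=d["reference_strain"],
                linear_limit=d.get("linear_limit", DEFAULT_TRANSITION_STRAIN / 2.0),
                stiffness_scale=d.get("stiffness_scale", 1.0),
            )
            for d in data["bundles"]
        ]
        return LigamentApparatus(bundles)
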