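"""Unsensed structural compliance of the upper (gimbal) actuator.

Under vertical contact load the gimbal arm segments and their bearings
deflect elastically.  The simulator's angle sensors do not register that
deflection, so the sensed relative implant pose drifts proximally with
respect to the true pose by the load-dependent deflection ``s(F)``.

The measured load–deflection behaviour is degressive up to a break load and
linear beyond it.  We model it as a power law matched C1 to a straight
line:

    s(F) = s_b * (F / F_b)**p          0 <= F <= F_b,  p = m * F_b / s_b
    s(F) = s_b + m * (F - F_b)         F > F_b

The exponent ``p`` is fixed by continuity of the slope at the break load,
so the curve is calibrated entirely from three anchors: break load ``F_b``
(N), deflection at break ``s_b`` (mm) and linear slope ``m`` (mm/N).
Defaults are the 0-degree flexion-arm anchors (500 N, 0.7 mm, 0.0006 mm/N),
the arm orientation with the largest measured compliance.  Other arm angles
scale the whole curve by a configurable multiplicative factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ComplianceCurve", "calibrate", "RIGID"]

#: Placeholder per-arm-angle scale factors; only the 0-degree curve is
#: anchored by measurement, the rest are configurable stand-ins.
DEFAULT_ANGLE_SCALE = {0.0: 1.0, 30.0: 0.9, 60.0: 0.8, 90.0: 0.7}


@dataclass(frozen=True)
class ComplianceCurve:
    """Load -> unsensed vertical deflection law of the upper actuator."""

    break_load: float = 500.0  # F_b, N
    break_displacement: float = 0.7  # s_b, mm
    linear_slope: float = 0.0006  # m, mm per N
    angle_scale: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_ANGLE_SCALE))

    def __post_init__(self) -> None:
        if self.break_load <= 0 or self.break_displacement <= 0 or self.linear_slope <= 0:
            raise ValueError("compliance anchors (break load, displacement, slope) must be positive")
        if any(not 0 < v <= 1 for v in self.angle_scale.values()):
            raise ValueError("angle scale factors must lie in (0, 1]")

    @property
    def shape_exponent(self) -> float:
        """Power-law exponent p = m * F_b / s_b (C1 matching at the break load)."""
        return self.linear_slope * self.break_load / self.break_displacement

    def _scale(self, arm_angle: float) -> float:
        angles = sorted(self.angle_scale)
        if arm_angle in self.angle_scale:
            return self.angle_scale[arm_angle]
        if not angles[0] <= arm_angle <= angles[-1]:
            raise ValueError(f"arm angle {arm_angle} outside calibrated range {angles[0]}..{angles[-1]}")
        return float(np.interp(arm_angle, angles, [self.angle_scale[a] for a in angles]))

    def displacement_at_load(self, load: float | np.ndarray, arm_angle: float = 0.0) -> float | np.ndarray:
        """Unsensed deflection s (mm) at vertical load F (N)."""
        f = np.asarray(load, dtype=float)
        if np.any(f < 0):
            raise ValueError("load must be nonnegative")
        p = self.shape_exponent
        with np.errstate(invalid="ignore"):
            toe = self.break_displacement * (f / self.break_load) ** p
        lin = self.break_displacement + self.linear_slope * (f - self.break_load)
        s = np.where(f <= self.break_load, toe, lin) * self._scale(arm_angle)
        return float(s) if s.ndim == 0 else s

    def load_at_displacement(self, displacement: float | np.ndarray, arm_angle: float = 0.0) -> float | np.ndarray:
        """Inverse: vertical load F (N) producing deflection s (mm)."""
        s = np.asarray(displacement, dtype=float) / self._scale(arm_angle)
        if np.any(s < 0):
            raise ValueError("displacement must be nonnegative")
        p = self.shape_exponent
        toe = self.break_load * np.where(s > 0, s / self.break_displacement, 0.0) ** (1.0 / p)
        lin = self.break_load + (s - self.break_displacement) / self.linear_slope
        f = np.where(s <= self.break_displacement, toe, lin)
        return float(f) if f.ndim == 0 else f

    # -- I/O -----------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "break_load_N": self.break_load,
                    "break_displacement_mm": self.break_displacement,
                    "linear_slope_mm_per_N": self.linear_slope,
                    "shape_exponent": self.shape_exponent,
                    "angle_scale": {str(k): v for k, v in self.angle_scale.items()},
                },
                indent=2,
            )
        )

    @staticmethod
    def from_json(path: str | Path) -> "ComplianceCurve":
        d = json.loads(Path(path).read_text())
        return ComplianceCurve(
            break_load=d["break_load_N"],
            break_displacement=d["break_displacement_mm"],
            linear_slope=d["linear_slope_mm_per_N"],
            angle_scale={float(k): v for k, v in d["angle_scale"].items()},
        )

    def tabulate(self, loads: np.ndarray | None = None, arm_angles: tuple[float, ...] = (0.0,)) -> pd.DataFrame:
        """Tabulate s(F) per arm angle, e.g. for plotting the calibration."""
        if loads is None:
            loads = np.linspace(0.0, 3000.0, 301)
        frames = []
        for a in arm_angles:
            frames.append(
                pd.DataFrame(
                    {
                        "load_N": loads,
                        "arm_angle_deg": a,
                        "displacement_mm": self.displacement_at_load(loads, a),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


class _RigidCurve(ComplianceCurve):
    """Zero-compliance stand-in: a perfectly stiff actuator."""

    def displacement_at_load(self, load, arm_angle: float = 0.0):
        f = np.asarray(load, dtype=float)
        out = np.zeros_like(f)
        return float(out) if out.ndim == 0 else out

    def load_at_displacement(self, displacement, arm_angle: float = 0.0):
        raise NotImplementedError("rigid curve has no load-displacement inverse")


#: Sentinel curve with zero deflection at any load (compliance disabled).
RIGID: ComplianceCurve = _RigidCurve()


def calibrate(
    break_load: float = 500.0,
    break_displacement: float = 0.7,
    linear_slope: float = 0.0006,
    angle_scale: dict[float, float] | None = None,
) -> ComplianceCurve:
    """Build a compliance curve from its three measured anchors."""
    kwargs = {} if angle_scale is None else {"angle_scale": angle_scale}
    return ComplianceCurve(break_load, break_displacement, linear_slope, **kwargs)
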