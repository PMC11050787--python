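"""Flexion-sweep result records shared by the reference model and emulator.

One row per flexion angle with the quantities reported for passive-flexion
testing: axial contact force along the tibial mechanical axis, tibial
internal/external rotation and femoral AP displacement (both expressed
relative to the 0-degree reference configuration, femoral AP = negated
tibial AP coordinate), the unsensed actuator deflection, and solver
diagnostics.  Per-bundle ligament forces are carried both as sensed by the
machine (compliance-corrupted pose) and true; for the rigid reference
model the two coincide.

Sign conventions (right knee): anterior, medial, proximal and tibial
internal rotation positive; femoral AP positive anterior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["FlexionResult", "run_schedule"]

_CSV_HEADER_COMMENT = (
    "# vivolig flexion sweep; right-knee Grood-Suntay convention: anterior/medial/"
    "proximal and tibial internal rotation positive; femoral_ap_mm = -tibial AP, "
    "relative to the 0-deg reference configuration; units mm, deg, N\n"
)


@dataclass
class FlexionResult:
    """Per-flexion-angle record of a passive flexion sweep."""

    table: pd.DataFrame
    bundle_forces_true: pd.DataFrame
    bundle_forces_sensed: pd.DataFrame
    meta: dict = field(default_factory=dict)
    aborted: bool = False

    def write(self, out_dir: str | Path, name: str) -> dict[str, Path]:
        """Write the run as CSV tables plus a JSON summary; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        main = out / f"{name}.csv"
        with open(main, "w") as fh:
            fh.write(_CSV_HEADER_COMMENT)
            self.table.to_csv(fh, index=False, lineterminator="\n", float_format="%.6f")
        paths["table"] = main
        for label, df in (("true", self.bundle_forces_true), ("sensed", self.bundle_forces_sensed)):
            p = out / f"{name}_bundle_forces_{label}.csv"
            df.to_csv(p, index=False, lineterminator="\n", float_format="%.6f")
            paths[f"bundle_forces_{label}"] = p
        summary_path = out / f"{name}_summary.json"
        summary_path.write_text(json.dumps(self.summary(), indent=2, sort_keys=True))
        paths["summary"] = summary_path
        return paths

    def summary(self) -> dict:
        t = self.table
        return {
            "meta": self.meta,
            "aborted": self.aborted,
            "n_steps": int(len(t)),
            "n_converged": int(t["converged"].sum()),
            "axial_force_N": {
                "at_0deg": float(t["axial_force_N"].iloc[0]),
                "at_end": float(t["axial_force_N"].iloc[-1]),
                "mean": float(t["axial_force_N"].mean()),
                "max": float(t["axial_force_N"].max()),
                "min": float(t["axial_force_N"].min()),
            },
            "femoral_ap_mm": {
                "at_end": float(t["femoral_ap_mm"].iloc[-1]),
                "max": float(t["femoral_ap_mm"].max()),
                "min": float(t["femoral_ap_mm"].min()),
            },
            "tibial_ie_deg": {
                "at_end": float(t["tibial_ie_deg"].iloc[-1]),
                "range": float(t["tibial_ie_deg"].max() - t["tibial_ie_deg"].min()),
            },
        }


def run_schedule(
    schedule,
    step_solver,
    initial_pose,
    min_step_deg: float = 0.25,
    max_flagged: int = 3,
):
    """Continuation over a flexion schedule with warm starts and step halving.

    ``step_solver(flexion_deg, warm_pose, prev_state) -> (EquilibriumResult,
    extras, state)`` solves one angle; ``state`` is whatever the solver needs
    carried between accepted steps (e.g. the previous transform for friction
    and the previous actuator deflection).  On non-convergence the interval
    to the next scheduled angle is bisected down to ``min_step_deg``; after
    ``max_flagged`` consecutive flagged scheduled steps the sweep aborts
    with a partial result.

    Returns ``(records, aborted)`` where records is a list of
    ``(flexion, EquilibriumResult, extras)`` for scheduled angles only.
    """
    schedule = list(schedule)
    if any(b - a <= 0 for a, b in zip(schedule, schedule[1:])):
        raise ValueError("flexion schedule must be strictly increasing")
    records = []
    pose = initial_pose
    state = None
    flagged_run = 0
    current = None
    for target in schedule:
        if current is None:
            res, extras, state = step_solver(target, pose, state)
        else:
            res, extras, state = _advance(step_solver, current, target, pose, state, min_step_deg)
        pose = res.pose
        current = target
        records.append((target, res, extras))
        flagged_run = 0 if res.converged else flagged_run + 1
        if flagged_run >= max_flagged:
            return records, True
    return records, False


def _advance(step_solver, start, target, pose, state, min_step):
    """Try the full step; bisect recursively on failure."""
    res, extras, new_state = step_solver(target, pose, state)
    if res.converged or (target - start) <= min_step:
        return res, extras, new_state
    mid = 0.5 * (start + target)
    res_mid, _, state_mid = _advance(step_solver, start, mid, pose, state, min_step)
    return _advance(step_solver, mid, target, res_mid.pose, state_mid, min_step)
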