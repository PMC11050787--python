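"""End-to-end experiment drivers: bench worked example, preload comparison,
PCL-resection sweep.

Each experiment takes a configuration dictionary (usually loaded from
YAML), builds the synthetic fixtures, runs the models and writes CSV
tables plus a JSON summary validated against the bundled summary schema.
Re-running an experiment with an identical configuration reproduces
byte-identical CSV output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compliance import RIGID
from .contact import ContactEngine, ContactLaw
from .emulator import (
    FlexionProtocol,
    run_passive_flexion,
    set_reference_configuration,
    worked_example_force_vs_load,
)
from .reference_model import ReferenceRunSpec, find_reference_state, run_reference_flexion
from .synthdata import (
    FixtureSpec,
    default_compliance_curve,
    make_exemplary_lcl_fixture,
    make_implant_surfaces,
    make_ligament_set,
    nominal_reference_pose,
)

__all__ = ["run_experiment", "load_config", "validate_summary", "BENCH_MEASUREMENTS"]

EXPERIMENTS = ("worked_example", "flexion_compare", "pcl_sweep")

#: Bench measurements reported for the physical simulator's compliance
#: study, used as validation anchors for the worked example: ligament force
#: at the reference configuration, at maximum unsensed deflection, and the
#: deflection anchors themselves.
BENCH_MEASUREMENTS = {
    "start_force_N": 268.0,
    "end_force_N": 108.0,
    "max_deflection_mm": 2.2,
    "deflection_at_500N_mm": 0.7,
    "linear_gradient_mm_per_N": 0.0006,
}

_SCHEMA_PATH = Path(__file__).with_name("summary_schema.json")


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or cfg.get("experiment") not in EXPERIMENTS:
        raise ValueError(f"config must set 'experiment' to one of {EXPERIMENTS}")
    return cfg


def validate_summary(summary: dict) -> None:
    """Structural validation of an experiment summary against the bundled schema.

    Checks required keys and primitive types recursively; raises
    ``ValueError`` on the first violation.
    """
    schema = json.loads(_SCHEMA_PATH.read_text())
    _check(summary, schema["common"], "summary")
    extra = schema["per_experiment"].get(summary.get("experiment", ""), {})
    _check(summary, extra, "summary")


_TYPES = {"string": str, "number": (int, float), "object": dict, "array": list, "boolean": bool}


def _check(obj: dict, spec: dict, path: str) -> None:
    for key, expected in spec.items():
        if key not in obj:
            raise ValueError(f"{path}.{key} missing")
        val = obj[key]
        if isinstance(expected, dict):
            if not isinstance(val, dict):
                raise ValueError(f"{path}.{key} must be an object")
            _check(val, expected, f"{path}.{key}")
        else:
            if not isinstance(val, _TYPES[expected]):
                raise ValueError(f"{path}.{key} must be {expected}")


def _schedule(cfg: dict) -> list[float]:
    p = cfg.get("protocol", {})
    start = float(p.get("flexion_start", 0.0))
    stop = float(p.get("flexion_stop", 80.0))
    step = float(p.get("flexion_step", 1.0))
    n = int(round((stop - start) / step))
    return [start + i * step for i in range(n + 1)]


def _fixtures(cfg: dict):
    f = cfg.get("fixture", {})
    spec = FixtureSpec(
        resolution=float(f.get("resolution", 1.0)),
        ligament_seed=int(f.get("ligament_seed", cfg.get("seed", 0))),
        ligament_jitter_mm=float(f.get("jitter_mm", 0.0)),
    )
    femoral, tibial = make_implant_surfaces(spec)
    apparatus = make_ligament_set(seed=spec.ligament_seed, jitter_mm=spec.ligament_jitter_mm)
    c = cfg.get("contact", {})
    law = ContactLaw(
        foundation_modulus=float(c.get("foundation_modulus", 30.0)),
        friction_mu=float(c.get("friction_mu", 0.04)),
    )
    return spec, femoral, tibial, apparatus, law


def run_experiment(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run one named experiment; returns the (schema-valid) summary dict.

    ``config`` is a dict or a path to a YAML file; ``output_dir``
    overrides the configured output directory.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    out = Path(output_dir or cfg.get("output_dir", "vivolig_out"))
    out.mkdir(parents=True, exist_ok=True)
    name = cfg["experiment"]
    summary = _RUNNERS[name](cfg, out)
    summary["experiment"] = name
    validate_summary(summary)
    (out / f"{name}_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _run_worked_example(cfg: dict, out: Path) -> dict:
    curve = default_compliance_curve()
    bundle = make_exemplary_lcl_fixture()
    loads = np.linspace(float(cfg.get("load_min", 30.0)), float(cfg.get("load_max", 3000.0)), int(cfg.get("n_loads", 100)))
    table = worked_example_force_vs_load(bundle, curve, loads)
    table.to_csv(out / "worked_example.csv", index=False, lineterminator="\n", float_format="%.6f")
    # pretension at the reference configuration (before any unsensed
    # deflection); the bench zeroes its displacement there
    from .ligaments import force_from_strain

    start = float(force_from_strain(bundle.reference_strain, bundle.stiffness_k, bundle.linear_limit))
    end = float(table.sensed_force_N.iloc[-1])
    s1_max = float(table.s1_mm.iloc[-1])
    computed = {
        "start_force_N": start,
        "end_force_N": end,
        "max_deflection_mm": s1_max,
        "deflection_at_500N_mm": float(curve.displacement_at_load(500.0)),
        "linear_gradient_mm_per_N": float(
            (curve.displacement_at_load(3000.0) - curve.displacement_at_load(2000.0)) / 1000.0
        ),
        "relative_reduction_pct": 100.0 * (end - start) / start,
    }
    checks = {
        key: {
            "computed": computed[key],
            "bench": BENCH_MEASUREMENTS[key],
            "within_2pct": bool(abs(computed[key] - BENCH_MEASUREMENTS[key]) <= 0.02 * abs(BENCH_MEASUREMENTS[key])),
        }
        for key in BENCH_MEASUREMENTS
    }
    return {"computed": computed, "bench_checks": checks, "n_loads": int(len(loads))}


def _run_flexion_compare(cfg: dict, out: Path) -> dict:
    spec, femoral, tibial, apparatus, law = _fixtures(cfg)
    schedule = _schedule(cfg)
    engine = ContactEngine(tibial, femoral, law)
    reference_pose, _ = find_reference_state(apparatus, engine, nominal_reference_pose(spec))
    curve = default_compliance_curve() if cfg.get("compliance", True) else RIGID
    ref_spec = ReferenceRunSpec(
        schedule=schedule, apparatus=apparatus, tibial_surface=tibial, femoral_surface=femoral, contact_law=law
    )
    ref = run_reference_flexion(ref_spec, reference_pose=reference_pose)
    ref.write(out, "reference")
    runs = {"reference": ref}
    for preload in cfg.get("preloads", [800.0, 100.0]):
        rc = set_reference_configuration(reference_pose, float(preload), curve, apparatus)
        proto = FlexionProtocol(schedule=tuple(schedule), preload=float(preload))
        r = run_passive_flexion(proto, rc, engine)
        tag = f"emulator_preload_{int(preload)}N"
        r.write(out, tag)
        runs[tag] = r
    # deviation table against the reference model
    dev = pd.DataFrame({"flexion_deg": ref.table.flexion_deg})
    for tag, r in runs.items():
        if tag == "reference":
            continue
        d = r.table.axial_force_N.values - ref.table.axial_force_N.values
        dev[f"{tag}_dforce_N"] = d
        with np.errstate(divide="ignore", invalid="ignore"):
            dev[f"{tag}_dforce_pct"] = 100.0 * d / ref.table.axial_force_N.values
        dev[f"{tag}_dap_mm"] = r.table.femoral_ap_mm.values - ref.table.femoral_ap_mm.values
        dev[f"{tag}_die_deg"] = r.table.tibial_ie_deg.values - ref.table.tibial_ie_deg.values
    dev.to_csv(out / "deviation_table.csv", index=False, lineterminator="\n", float_format="%.6f")
    if cfg.get("plots", False):
        _plot_flexion_compare(runs, out)
    return {
        "runs": {
            tag: {
                "axial_force_at_0deg_N": float(r.table.axial_force_N.iloc[0]),
                "axial_force_at_end_N": float(r.table.axial_force_N.iloc[-1]),
                "all_converged": bool(r.table.converged.all()),
            }
            for tag, r in runs.items()
        },
        "n_steps": int(len(schedule)),
    }


def _run_pcl_sweep(cfg: dict, out: Path) -> dict:
    spec, femoral, tibial, apparatus, law = _fixtures(cfg)
    schedule = _schedule(cfg)
    scales = [float(s) for s in cfg.get("scales", [1.0, 0.5, 0.25, 0.0])]
    models = list(cfg.get("models", ["reference", "emulator"]))
    engine = ContactEngine(tibial, femoral, law)
    reference_pose, _ = find_reference_state(apparatus, engine, nominal_reference_pose(spec))
    curve = default_compliance_curve()
    preload = float(cfg.get("preload", 800.0))
    per_model: dict[str, dict] = {}
    for model in models:
        results = []
        for s in scales:
            app = apparatus.copy()
            if model == "reference":
                rs = ReferenceRunSpec(
                    schedule=schedule,
                    apparatus=app,
                    tibial_surface=tibial,
                    femoral_surface=femoral,
                    contact_law=law,
                    pcl_scale=s,
                )
                r = run_reference_flexion(rs, reference_pose=reference_pose)
            elif model == "emulator":
                rc = set_reference_configuration(reference_pose, preload, curve, app)
                rc.apparatus.set_resection("PCL", s)
                proto = FlexionProtocol(schedule=tuple(schedule), preload=preload)
                r = run_passive_flexion(proto, rc, engine)
            else:
                raise ValueError(f"unknown model {model!r}")
            r.write(out, f"pcl_{model}_scale_{int(round(100 * s))}pct")
            results.append(r)
        base, rest = results[0], results[-1]
        per_model[model] = {
            "axial_force_at_80deg_by_scale_N": {
                str(s): float(r.table.axial_force_N.iloc[-1]) for s, r in zip(scales, results)
            },
            "femoral_ap_at_80deg_by_scale_mm": {
                str(s): float(r.table.femoral_ap_mm.iloc[-1]) for s, r in zip(scales, results)
            },
            "force_difference_at_80deg_N": float(
                base.table.axial_force_N.iloc[-1] - rest.table.axial_force_N.iloc[-1]
            ),
            "ap_difference_at_80deg_mm": float(
                abs(base.table.femoral_ap_mm.iloc[-1] - rest.table.femoral_ap_mm.iloc[-1])
            ),
        }
    return {"models": per_model, "scales": [str(s) for s in scales], "n_steps": int(len(schedule))}


def _plot_flexion_compare(runs: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(6, 10), sharex=True)
    for tag, r in runs.items():
        t = r.table
        axes[0].plot(t.flexion_deg, t.axial_force_N, label=tag)
        axes[1].plot(t.flexion_deg, t.tibial_ie_deg, label=tag)
        axes[2].plot(t.flexion_deg, t.femoral_ap_mm, label=tag)
    axes[0].set_ylabel("axial contact force (N)")
    axes[1].set_ylabel("tibial IE rotation (deg)")
    axes[2].set_ylabel("femoral AP displacement (mm)")
    axes[2].set_xlabel("flexion (deg)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "flexion_compare.png", dpi=150)
    plt.close(fig)


_RUNNERS = {
    "worked_example": _run_worked_example,
    "flexion_compare": _run_flexion_compare,
    "pcl_sweep": _run_pcl_sweep,
}
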